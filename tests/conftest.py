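"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tubesta import (
    DensityVolume,
    EulerTriplet,
    LatticeSpec,
    TubeModel,
    euler_to_matrix,
    matrix_to_euler,
    render_motif,
)
from tubesta.simulator import ARCH_HEIGHT_A, build_ground_truth, _straight_tube


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def gaussian_blob():
    """Smooth 32-cube phantom for interpolation-tolerance tests."""
    n = 32
    zz, yy, xx = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
    data = np.exp(-((xx - 2.0) ** 2 + (yy + 3.0) ** 2 + zz**2) / (2 * 16.0))
    data += 0.5 * np.exp(-((xx + 5.0) ** 2 + yy**2 + (zz - 4.0) ** 2) / (2 * 9.0))
    return DensityVolume(data.astype(np.float32), 8.0)


@pytest.fixture(scope="session")
def straight_tube():
    """Straight tube along y: radius 150 Å, length 440 Å at 8 Å voxels."""
    return _straight_tube((58.0, 58.0), 10.0, 55.0, 150.0, 0, 1)


def make_lattice(tilt_deg=22.0, jitter_A=0.0, jitter_deg=0.0, seed=7,
                 length_vox=16.5, shape=(116, 96, 116), units_per_turn=10,
                 voxel=8.0, variant="default"):
    tube = _straight_tube((58.0, 58.0), 40.0, length_vox, 150.0, 0, 1)
    motif = render_motif(voxel, variant)
    spec = LatticeSpec(
        tube=tube, axial_rise_A=80.0, units_per_turn=units_per_turn,
        arch_tilt_deg=tilt_deg, unit_density=motif, voxel_size_A=voxel,
        volume_shape=shape, jitter_A=jitter_A, jitter_deg=jitter_deg, seed=seed,
    )
    return spec, build_ground_truth(spec)


@pytest.fixture(scope="session")
def clean_lattice():
    """Jitter-free 22°-tilt coated tube: (spec, (truth_table, truth_volume))."""
    return make_lattice()


def seed_gauge_table(truth: pd.DataFrame, voxel: float, tilt_deg: float = 22.0):
    """Truth table re-expressed in the seeding gauge: positions at membrane
    anchors, orientations with z along the membrane normal."""
    t = np.deg2rad(tilt_deg)
    rx = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])
    out = truth.copy()
    for i in out.index:
        r_u = euler_to_matrix(EulerTriplet(*out.loc[i, ["phi", "theta", "psi"]]))
        anchor = out.loc[i, ["pos_x", "pos_y", "pos_z"]].to_numpy(float) - (
            ARCH_HEIGHT_A / voxel
        ) * (r_u @ np.array([0.0, 0.0, 1.0]))
        out.loc[i, ["pos_x", "pos_y", "pos_z"]] = anchor
        out.loc[i, ["phi", "theta", "psi"]] = matrix_to_euler(r_u @ rx.T).as_tuple()
    return out
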