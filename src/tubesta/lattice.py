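"""Lattice-geometry analysis of refined particle tables: arch tilt relative to
the membrane perpendicular, and neighbor/regularity statistics."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .geometry import EulerTriplet, TubeModel, euler_to_matrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class LatticeStats:
    per_particle: pd.DataFrame
    tilt_mean_deg: float | None = None
    tilt_sd_deg: float | None = None
    n_excluded: int = 0
    modal_spacing_A: float | None = None
    regularity_index: float | None = None


def circular_mean_deg(angles_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean and SD (degrees) of a set of angles."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    c, s = np.cos(a).mean(), np.sin(a).mean()
    rbar = float(np.hypot(c, s))
    mean = float(np.rad2deg(np.arctan2(s, c))) % 360.0
    sd = float(np.rad2deg(np.sqrt(max(-2.0 * np.log(max(rbar, 1e-12)), 0.0))))
    return mean, sd


def _local_normal(pos_xyz: np.ndarray, tube: TubeModel) -> np.ndarray:
    center, axis = tube.project(pos_xyz)
    radial = pos_xyz - center
    radial = radial - (radial @ axis) * axis
    n = np.linalg.norm(radial)
    if n < 1e-9:
        raise ValidationError("particle on the tube centerline; normal undefined")
    return radial / n


def arch_tilt_stats(
    table: pd.DataFrame, tubes: list, voxel_size_A: float
) -> LatticeStats:
    """Per-particle tilt of the arch axis away from the membrane perpendicular.

    The arch axis is the particle frame's z-axis after final refinement (the
    reference having been recentered so the arch defines that axis); the
    perpendicular is the outward radial direction of the particle's tube at
    its refined position, so a perfectly upright arch scores 0°.  Particles
    farther than twice the tube radius from their tube axis are excluded.
    """
    by_tube = {t.tube_id: t for t in tubes}
    rows = []
    n_excluded = 0
    for idx in table.index:
        rec = table.loc[idx]
        tube = by_tube.get(int(rec["tube_id"]))
        if tube is None:
            n_excluded += 1
            continue
        pos = rec[["pos_x", "pos_y", "pos_z"]].to_numpy(dtype=float)
        center, axis = tube.project(pos)
        radial = pos - center
        radial = radial - (radial @ axis) * axis
        dist_A = np.linalg.norm(radial) * voxel_size_A
        if dist_A > 2.0 * tube.radius_A or dist_A < 1e-6:
            n_excluded += 1
            continue
        normal = radial / np.linalg.norm(radial)
        r = euler_to_matrix(EulerTriplet(rec["phi"], rec["theta"], rec["psi"]))
        zaxis = r @ np.array([0.0, 0.0, 1.0])
        tilt = float(np.rad2deg(np.arccos(np.clip(zaxis @ normal, -1.0, 1.0))))
        rows.append({"particle_id": int(rec["particle_id"]), "tilt_deg": tilt,
                     "tube_id": int(rec["tube_id"])})
    if n_excluded:
        logger.info("arch_tilt_stats: excluded %d particles", n_excluded)
    per = pd.DataFrame(rows)
    if len(per) == 0:
        return LatticeStats(per, n_excluded=n_excluded)
    mean, sd = circular_mean_deg(per["tilt_deg"].to_numpy())
    if mean > 180.0:
        mean -= 360.0
    return LatticeStats(per, tilt_mean_deg=mean, tilt_sd_deg=sd, n_excluded=n_excluded)


def neighbor_stats(
    table: pd.DataFrame,
    radius_A: float,
    voxel_size_A: float,
    tubes: list | None = None,
    spacing_tolerance: float = 0.15,
) -> LatticeStats:
    """Neighbor displacement vectors and a lattice-regularity index.

    Neighbors are particle pairs of the same tomogram within ``radius_A``
    (a symmetric relation).  When tube models are given, displacement vectors
    are expressed in the local surface frame (circumferential, axial, radial
    components).  The regularity index is the fraction of particles whose
    nearest-neighbor distance lies within ±15% of the modal distance.
    """
    by_tube = {t.tube_id: t for t in tubes} if tubes else {}
    recs = []
    nn_dists = []
    for tomo, sub in table.groupby("tomo_id"):
        pos = sub[["pos_x", "pos_y", "pos_z"]].to_numpy(dtype=float) * voxel_size_A
        pids = sub["particle_id"].to_numpy()
        if len(pos) < 2:
            continue
        tree = cKDTree(pos)
        pairs = tree.query_pairs(radius_A, output_type="ndarray")
        neigh: dict[int, list] = {i: [] for i in range(len(pos))}
        for i, j in pairs:
            neigh[i].append(j)
            neigh[j].append(i)
        for i in range(len(pos)):
            if not neigh[i]:
                continue
            rec_i = sub.iloc[i]
            frame = None
            tube = by_tube.get(int(rec_i["tube_id"]))
            if tube is not None:
                try:
                    n = _local_normal(pos[i] / voxel_size_A, tube)
                    _, axis = tube.project(pos[i] / voxel_size_A)
                    t = np.cross(axis, n)
                    t /= np.linalg.norm(t)
                    frame = np.stack([t, axis, n])  # rows: circ, axial, radial
                except ValidationError:
                    frame = None
            dmin = np.inf
            for j in neigh[i]:
                d = pos[j] - pos[i]
                dist = float(np.linalg.norm(d))
                dmin = min(dmin, dist)
                local = frame @ d if frame is not None else d
                recs.append({
                    "particle_id": int(pids[i]),
                    "neighbor_id": int(pids[j]),
                    "distance_A": dist,
                    "d_circ_A": float(local[0]),
                    "d_axial_A": float(local[1]),
                    "d_radial_A": float(local[2]),
                })
            nn_dists.append(dmin)
    per = pd.DataFrame(recs)
    if not nn_dists:
        logger.warning("neighbor_stats: no neighbor pairs within %.0f Å", radius_A)
        return LatticeStats(per)
    nn = np.asarray(nn_dists)
    hist, edges = np.histogram(nn, bins=max(8, int(np.ptp(nn) / 4.0) + 1))
    modal = float(0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]))
    reg = float(np.mean(np.abs(nn - modal) <= spacing_tolerance * modal))
    return LatticeStats(per, modal_spacing_A=modal, regularity_index=reg)
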