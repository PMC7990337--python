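"""Synthetic coated-tube generator: ground-truth lattices on membrane tubules,
density rendering, wedge/CTF/exposure-affected noisy subtomograms, miniature
tomograms, and ready-made on-disk fixtures.

Two tiers of realism are provided.  The fast path collapses the tomographic
forward model to a Fourier-mask multiplication (missing wedge + CTF amplitude
+ exposure filter) applied to the clean density, followed by additive noise;
this reproduces the anisotropic information loss that drives wedge-aware
alignment.  The full path projects the phantom through a dose-symmetric tilt
scheme and reconstructs it by weighted backprojection, and is used to check
that the fast surrogate is faithful.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree

from . import io_formats
from .errors import ExtractionError, ValidationError
from .fourier_filters import (
    CTFProfile,
    FourierMask,
    binary_wedge,
    composite_particle_mask,
    ctf_amplitude_profile,
    exposure_filter,
)
from .geometry import TubeModel, _transported_frames, frame_on_surface, rotate_array
from .io_formats import DensityVolume, TiltScheme, dose_symmetric_scheme, new_particle_table

logger = logging.getLogger(__name__)

# membrane bilayer: two Gaussian head-group shells straddling the mid-plane
MEMBRANE_SEPARATION_A = 40.0
MEMBRANE_SIGMA_A = 7.0
MEMBRANE_AMPLITUDE = 1.0

# height of the arch density centroid above the bilayer mid-plane
ARCH_HEIGHT_A = 70.0

# --------------------------------------------------------------------------
# Arch motif: a ~150 Å arch built from ellipsoidal Gaussian lobes
# --------------------------------------------------------------------------

# (center_xyz_A, sigma_xyz_A, amplitude); motif frame: z = arch axis
# (membrane -> apex), x = circumferential span.  Two identical legs plus an
# apex "head" of three equal lobes on an equilateral triangle: every slice
# perpendicular to the arch axis has its centroid exactly on the axis (the
# property the recentering estimator relies on, preserved under any centered
# circular window), while the C3 head combined with the C2 leg pair leaves no
# in-plane symmetry, so particle orientations are unambiguous.
_TRI_R, _TRI_Z = 22.0, 24.0
_BASE_LOBES = [
    ((-39.0, 0.0, -28.0), (11.0, 11.0, 20.0), 1.0),   # leg
    ((+39.0, 0.0, -28.0), (11.0, 11.0, 20.0), 1.0),   # leg
] + [
    # apex head (C3): breaks the two-fold in-plane symmetry while keeping the
    # motif mirror-symmetric about the y-z plane (an achiral default keeps
    # the in-plane correlation landscape single-peaked)
    ((_TRI_R * np.cos(np.deg2rad(az)), _TRI_R * np.sin(np.deg2rad(az)), _TRI_Z),
     (10.0, 10.0, 11.0), 0.75)
    for az in (90.0, 210.0, 330.0)
]


def arch_motif_lobes(variant: str = "default") -> list:
    """Gaussian-lobe description of the arch motif.

    Variants: ``default``; ``short_leg`` (one leg shortened by 20%, the
    structural difference used by two-class fixtures); ``short_leg_mirror``
    (its x-mirror image — the shortened leg makes the motif chiral, so the
    mirrored pair are genuinely opposite-handedness variants).
    Lobes are recentred so the density centroid sits exactly on the motif
    z-axis — the axis the recentering estimator reads off an average.
    """
    lobes = [list(map(list, (c, s))) + [a] for c, s, a in _BASE_LOBES]
    if variant in ("short_leg", "short_leg_mirror"):
        c, s, a = lobes[1]
        s[2] *= 0.8  # 20% shorter leg
        c[2] -= 0.2 * s[2]
        if variant == "short_leg_mirror":
            for c, s, a in lobes:
                c[0] = -c[0]
    elif variant != "default":
        raise ValidationError(f"unknown motif variant {variant!r}")
    masses = np.array([a * s[0] * s[1] * s[2] for c, s, a in lobes])
    centers = np.array([c for c, s, a in lobes])
    com = (masses[:, None] * centers).sum(0) / masses.sum()
    out = []
    for (c, s, a) in lobes:
        out.append((tuple(np.asarray(c) - com), tuple(s), a))
    return out


def render_motif(
    voxel_size_A: float, variant: str = "default", box: int | None = None
) -> DensityVolume:
    """Render the arch motif on a cubic grid centred on its centroid."""
    lobes = arch_motif_lobes(variant)
    if box is None:
        extent = max(
            abs(c[j]) + 3.0 * s[j] for c, s, _ in lobes for j in range(3)
        )
        box = int(np.ceil(2 * extent / voxel_size_A / 2.0)) * 2 + 4
    zz, yy, xx = np.meshgrid(*[np.arange(box) - box // 2] * 3, indexing="ij")
    coords = np.stack([xx, yy, zz]) * voxel_size_A
    data = np.zeros((box, box, box), dtype=np.float64)
    for c, s, a in lobes:
        q = sum(((coords[j] - c[j]) / s[j]) ** 2 for j in range(3))
        data += a * np.exp(-0.5 * q)
    return DensityVolume(data.astype(np.float32), voxel_size_A)


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------


@dataclasses.dataclass
class LatticeSpec:
    """Ground-truth pseudohelical coat lattice on one tube.

    ``unit_density`` may be a single motif or a list of variants; with a list,
    each unit is assigned a variant (uniformly at random from ``seed``)
    and the assignment recorded as the ground-truth class label.
    ``jitter_deg`` is the per-axis SD of a small random rotation vector.
    """

    tube: TubeModel
    axial_rise_A: float
    units_per_turn: int
    arch_tilt_deg: float
    unit_density: DensityVolume | list
    voxel_size_A: float
    volume_shape: tuple[int, int, int]
    jitter_A: float = 0.0
    jitter_deg: float = 0.0
    seed: int = 0
    arch_height_A: float = ARCH_HEIGHT_A
    stagger_frac: float = 0.5  # per-ring azimuthal offset, in unit spacings

    def __post_init__(self) -> None:
        if not 0 <= self.arch_tilt_deg < 90:
            raise ValidationError("arch_tilt_deg must lie in [0, 90)")
        if self.jitter_A < 0 or self.jitter_deg < 0:
            raise ValidationError("jitter values must be non-negative")

    def variants(self) -> list:
        u = self.unit_density
        return list(u) if isinstance(u, (list, tuple)) else [u]


@dataclasses.dataclass
class NoiseModel:
    """Additive detector-referred noise at a requested SNR.

    SNR is the ratio of clean-signal variance (after Fourier-mask filtering)
    to noise variance.  ``colored`` switches from white to 1/k-weighted noise.
    """

    snr: float
    colored: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValidationError("snr must be positive (use numpy.inf for none)")


def _noise_field(shape, rng: np.random.Generator, colored: bool) -> np.ndarray:
    white = rng.standard_normal(shape)
    if not colored:
        return white
    f = np.fft.fftn(white)
    kz, ky, kx = np.meshgrid(*[np.fft.fftfreq(n) * n for n in shape], indexing="ij")
    kmag = np.sqrt(kx**2 + ky**2 + kz**2)
    f /= np.maximum(kmag, 1.0)
    field = np.fft.ifftn(f).real
    return field / field.std()


# --------------------------------------------------------------------------
# Ground truth construction
# --------------------------------------------------------------------------


def _render_membrane(
    volume: np.ndarray, tube: TubeModel, voxel_size_A: float,
    extend_vox: float = 64.0,
) -> None:
    """Add two concentric Gaussian shells (bilayer head groups) around the tube.

    The centerline is extrapolated by ``extend_vox`` at both ends before
    rendering: real tubules extend beyond the reconstructed volume, and a
    finite membrane would otherwise end in bright hemispherical caps that
    masquerade as coat density.
    """
    dense = []
    arcs = tube.arc_lengths()
    t0 = tube.axis_at(0.0)
    t1 = tube.axis_at(arcs[-1])
    p0 = tube.centerline[0]
    p1 = tube.centerline[-1]
    for s in np.linspace(extend_vox, 0.25, max(int(extend_vox * 4), 8)):
        dense.append(p0 - s * t0)
        dense.append(p1 + s * t1)
    n_samp = max(int(arcs[-1] * 4), 8)
    for s in np.linspace(0, arcs[-1], n_samp):
        dense.append(tube.point_at(s))
    tree = cKDTree(np.asarray(dense))
    nz, ny, nx = volume.shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1).astype(np.float32)
    d_vox, _ = tree.query(pts, workers=-1)
    d_A = d_vox.reshape(volume.shape) * voxel_size_A
    half = MEMBRANE_SEPARATION_A / 2.0
    for r_shell in (tube.radius_A - half, tube.radius_A + half):
        volume += MEMBRANE_AMPLITUDE * np.exp(
            -0.5 * ((d_A - r_shell) / MEMBRANE_SIGMA_A) ** 2
        )


def _splat(volume: np.ndarray, motif: np.ndarray, R: np.ndarray, pos_xyz) -> None:
    """Add ``motif`` rotated by R with its centre at float position pos_xyz."""
    n_m = motif.shape[0]
    out_n = int(np.ceil(n_m * 1.46 / 2.0)) * 2  # hold any rotation of the motif
    pos_idx = np.asarray(pos_xyz, dtype=float)[::-1]  # zyx
    base = np.round(pos_idx).astype(int) - out_n // 2
    perm = np.eye(3)[::-1]
    Minv = perm @ np.asarray(R, dtype=float).T @ perm
    c_m = np.full(3, n_m // 2, dtype=float)
    offset = Minv @ (base - pos_idx) + c_m
    block = ndimage.affine_transform(
        motif, Minv, offset=offset, output_shape=(out_n,) * 3,
        order=1, mode="constant", cval=0.0, prefilter=False,
    )
    lo = np.maximum(base, 0)
    hi = np.minimum(base + out_n, volume.shape)
    if np.any(lo >= hi):
        return
    src = tuple(slice(l - b, h - b) for l, h, b in zip(lo, hi, base))
    dst = tuple(slice(l, h) for l, h in zip(lo, hi))
    volume[dst] += block[src]


def build_ground_truth(spec: LatticeSpec) -> tuple[pd.DataFrame, DensityVolume]:
    """Render one coated tube and return its true particle table and volume.

    Units sit on rings every ``axial_rise_A`` with ``units_per_turn`` units per
    ring and a per-ring azimuthal stagger (a pseudohelical winding).  Each
    unit's frame is the membrane-surface frame composed with a rotation of
    ``arch_tilt_deg`` about the circumferential axis, plus jitter; its density
    centroid sits ``arch_height_A`` above the surface along its own z-axis.
    The table is exactly reproducible from (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    tube = spec.tube
    vx = spec.voxel_size_A
    variants = spec.variants()
    for v in variants:
        if abs(v.voxel_size_A - vx) > 1e-6:
            raise ValidationError("unit_density voxel size must match the lattice spec")
    volume = np.zeros(spec.volume_shape, dtype=np.float64)
    _render_membrane(volume, tube, vx)

    rise_vox = spec.axial_rise_A / vx
    length = tube.length_vox()
    arc_positions = np.arange(0.0, length - 1e-9, rise_vox)
    frames = _transported_frames(tube, arc_positions)
    r_vox = tube.radius_A / vx
    tilt = np.deg2rad(spec.arch_tilt_deg)
    R_tilt = np.array(
        [[1, 0, 0], [0, np.cos(tilt), -np.sin(tilt)], [0, np.sin(tilt), np.cos(tilt)]]
    )
    rows = []
    for k, (s, (a, u, w)) in enumerate(zip(arc_positions, frames)):
        center = tube.point_at(s)
        phase = 2 * np.pi * spec.stagger_frac * k / spec.units_per_turn
        for j in range(spec.units_per_turn):
            az = 2 * np.pi * j / spec.units_per_turn + phase
            n = np.cos(az) * u + np.sin(az) * w
            anchor = center + r_vox * n
            if spec.jitter_A > 0:
                anchor = anchor + rng.normal(0.0, spec.jitter_A / vx, 3)
            R_unit = frame_on_surface(a, n) @ R_tilt
            if spec.jitter_deg > 0:
                rv = np.deg2rad(rng.normal(0.0, spec.jitter_deg, 3))
                ang = np.linalg.norm(rv)
                if ang > 1e-12:
                    ax = rv / ang
                    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]],
                                  [-ax[1], ax[0], 0]])
                    R_unit = R_unit @ (
                        np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
                    )
            cls = int(rng.integers(len(variants))) if len(variants) > 1 else 0
            pos = anchor + (spec.arch_height_A / vx) * (R_unit @ np.array([0.0, 0.0, 1.0]))
            rows.append((pos, R_unit, cls))

    from .geometry import matrix_to_euler  # local import to avoid cycle at module load

    table = new_particle_table(len(rows))
    table["tomo_id"] = tube.tomo_id
    table["tube_id"] = tube.tube_id
    for i, (pos, R_unit, cls) in enumerate(rows):
        table.loc[i, ["pos_x", "pos_y", "pos_z"]] = pos
        table.loc[i, ["phi", "theta", "psi"]] = matrix_to_euler(R_unit).as_tuple()
        table.loc[i, "class_id"] = cls
        motif = variants[cls]
        _splat(volume, motif.data.astype(np.float64), R_unit, pos)
    return table, DensityVolume(volume.astype(np.float32), vx)


# --------------------------------------------------------------------------
# Subtomogram surrogate (Fourier-mask forward model)
# --------------------------------------------------------------------------


def extract_crop(volume: DensityVolume, pos_xyz, box: int) -> DensityVolume:
    """Cubic crop of ``box`` voxels centred at the rounded position."""
    c = np.round(np.asarray(pos_xyz, dtype=float)).astype(int)[::-1]  # zyx
    lo = c - box // 2
    hi = lo + box
    if (lo < 0).any() or (hi > np.asarray(volume.data.shape)).any():
        raise ExtractionError(
            f"crop at {tuple(np.asarray(pos_xyz))} with box {box} exceeds the tomogram"
        )
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return DensityVolume(volume.data[sl].copy(), volume.voxel_size_A)


def simulate_subtomogram(
    truth_volume: DensityVolume,
    record,
    box: int,
    mask: FourierMask,
    noise: NoiseModel,
) -> DensityVolume:
    """Fast forward model: crop -> Fourier mask -> additive noise.

    The record's true pose parameterizes nothing here (poses live in the
    table, never in the data); only its position and particle_id are used.
    Noise is seeded from (noise.seed, particle_id) so batches are reproducible
    and particles independent.
    """
    if box % 2:
        raise ValidationError("box must be even")
    pos = np.array([record["pos_x"], record["pos_y"], record["pos_z"]], dtype=float)
    crop = extract_crop(truth_volume, pos, box)
    f = np.fft.fftn(crop.data)
    f *= mask.unshifted()
    clean = np.fft.ifftn(f).real.astype(np.float32)
    if not np.isfinite(noise.snr):
        return DensityVolume(clean, truth_volume.voxel_size_A)
    rng = np.random.default_rng([noise.seed, int(record["particle_id"])])
    field = _noise_field(clean.shape, rng, noise.colored)
    sigma = np.sqrt(clean.var() / noise.snr)
    return DensityVolume(
        (clean + sigma * field).astype(np.float32), truth_volume.voxel_size_A
    )


def realized_snr(noisy: np.ndarray, clean: np.ndarray) -> float:
    """Clean-signal variance over residual-noise variance."""
    return float(clean.var() / (np.asarray(noisy) - clean).var())


def apply_wedge_to_volume(
    volume: DensityVolume, mask: FourierMask, noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None, signal_var: float | None = None,
) -> DensityVolume:
    """Wedge-collapse a whole phantom volume and optionally add noise.

    ``signal_var`` is the clean filtered-signal variance the SNR refers to
    (normally the mean variance of particle-sized crops, so the tomogram path
    and :func:`simulate_subtomogram` share one SNR definition).  When omitted
    it falls back to the variance over the structure region (voxels where the
    clean density exceeds 5% of max).
    """
    f = np.fft.fftn(volume.data)
    if mask.shape != volume.data.shape:
        raise ValidationError("mask shape must match the volume")
    filtered = np.fft.ifftn(f * mask.unshifted()).real.astype(np.float32)
    if noise is None or not np.isfinite(noise.snr):
        return DensityVolume(filtered, volume.voxel_size_A)
    if signal_var is None:
        region = np.abs(volume.data) > 0.05 * float(np.abs(volume.data).max())
        signal_var = float(filtered[region].var()) if region.any() else float(filtered.var())
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    shaped = _noise_field(filtered.shape, rng, noise.colored).astype(np.float32)
    return DensityVolume(
        filtered + np.float32(np.sqrt(signal_var / noise.snr)) * shaped,
        volume.voxel_size_A,
    )


def crop_signal_variance(filtered: DensityVolume, table: pd.DataFrame, box: int) -> float:
    """Mean variance of particle-sized crops of a clean (filtered) volume."""
    variances = []
    for _, rec in table.iterrows():
        try:
            c = extract_crop(filtered, rec[["pos_x", "pos_y", "pos_z"]].to_numpy(float), box)
        except ExtractionError:
            continue
        variances.append(float(c.data.var()))
    if not variances:
        return float(filtered.data.var())
    return float(np.mean(variances))


# --------------------------------------------------------------------------
# Full tilt-series forward model + weighted backprojection
# --------------------------------------------------------------------------


def project_tilt(volume: np.ndarray, angle_deg: float) -> np.ndarray:
    """Parallel projection along the beam at the given stage tilt (axis +y)."""
    rot = ndimage.rotate(
        volume, -angle_deg, axes=(0, 2), reshape=False, order=1,
        mode="constant", cval=0.0, prefilter=False,
    )
    return rot.sum(axis=0)


def simulate_tilt_series_tomogram(
    truth_volume: DensityVolume,
    scheme: TiltScheme,
    noise: NoiseModel,
    ctf_profile: CTFProfile | None = None,
    apply_exposure: bool = True,
) -> DensityVolume:
    """Project the phantom through the tilt scheme, filter each tilt by its
    cumulative exposure (and optional CTF amplitude), add per-tilt noise, and
    reconstruct by ramp-filtered (weighted) backprojection."""
    if np.any(np.abs(scheme.angles_deg) > 90):
        raise ValidationError("tilt angles must lie within ±90°")
    data = truth_volume.data.astype(np.float32)
    nz, ny, nx = data.shape
    if nz != nx:
        raise ValidationError("tilt-series simulation requires nz == nx")
    vx = truth_volume.voxel_size_A
    fy = np.fft.fftfreq(ny, d=vx)
    fx = np.fft.fftfreq(nx, d=vx)
    fmag2d = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    cum = scheme.cumulative_dose_eA2()
    ramp = np.abs(np.fft.fftfreq(nx))
    recon = np.zeros_like(data, dtype=np.float64)
    rng = np.random.default_rng(noise.seed)
    for i, alpha in enumerate(scheme.angles_deg):
        proj = project_tilt(data, float(alpha))
        filt2d = np.ones_like(fmag2d)
        if apply_exposure:
            filt2d = filt2d * exposure_filter(float(cum[i]), fmag2d)
        if ctf_profile is not None:
            filt2d = filt2d * ctf_profile(fmag2d)
        proj = np.fft.ifft2(np.fft.fft2(proj) * filt2d).real
        if np.isfinite(noise.snr):
            proj = proj + rng.standard_normal(proj.shape) * np.sqrt(
                proj.var() / noise.snr
            )
        filtered = np.fft.ifft(np.fft.fft(proj, axis=1) * ramp[None, :], axis=1).real
        smear = np.broadcast_to(filtered[None, :, :], (nz, ny, nx)).astype(np.float32)
        back = ndimage.rotate(
            smear, float(alpha), axes=(0, 2), reshape=False, order=1,
            mode="constant", cval=0.0, prefilter=False,
        )
        recon += back
    recon *= np.pi / (2.0 * max(scheme.n_tilts, 1))
    return DensityVolume(recon.astype(np.float32), vx)


# --------------------------------------------------------------------------
# Fixture bundles
# --------------------------------------------------------------------------

DEFAULT_OPTICS = {
    "defocus_um": 4.0,
    "voltage_kV": 300.0,
    "cs_mm": 2.7,
    "amplitude_contrast": 0.07,
}

DEFAULT_SCHEME = {"tilt_max_deg": 60.0, "n_tilts": 41, "total_dose_eA2": 130.0}

DEFAULT_LATTICE = {
    "axial_rise_A": 80.0,
    "arch_tilt_deg": 22.0,
    "arch_height_A": ARCH_HEIGHT_A,
    "jitter_A": 5.0,
    "jitter_deg": 3.0,
}


def _straight_tube(center_xz_vox, y0_vox, length_vox, radius_A, tomo_id, tube_id):
    cx, cz = center_xz_vox
    n_pts = max(int(length_vox // 4) + 2, 2)
    ys = np.linspace(y0_vox, y0_vox + length_vox, n_pts)
    line = np.stack([np.full_like(ys, cx), ys, np.full_like(ys, cz)], axis=1)
    return TubeModel(line, radius_A, tomo_id=tomo_id, tube_id=tube_id)


PRESETS = {
    # name: voxel, box, snr, tomograms [(shape_zyx, [(tube kwargs)...])]
    "tiny": {
        "voxel_size_A": 10.0,
        "boxsize": 24,
        "snr": 0.5,
        "radius_A": 75.0,
        "units_per_turn": 5,
        "variants": ["default"],
        "tomograms": [((64, 64, 64), [((32.0, 32.0), 22.0, 20.0)])],
    },
    "small": {
        "voxel_size_A": 8.0,
        "boxsize": 48,
        "snr": 0.5,
        "radius_A": 150.0,
        "units_per_turn": 10,
        "variants": ["default"],
        "tomograms": [
            ((116, 96, 208), [((58.0, 58.0), 40.0, 16.5), ((150.0, 58.0), 40.0, 16.5)]),
            ((116, 96, 116), [((58.0, 58.0), 37.0, 22.0)]),
        ],
    },
    "classes": {
        "voxel_size_A": 8.0,
        "boxsize": 48,
        "snr": 0.5,
        "radius_A": 150.0,
        "units_per_turn": 10,
        "variants": ["default", "short_leg"],
        "tomograms": [((116, 96, 116), [((58.0, 58.0), 38.0, 16.5)])],
    },
}
# per-tube entries above are ((center_x, center_z), y0_vox, length_vox)


@dataclasses.dataclass
class FixtureBundle:
    manifest: dict
    root: Path
    tomograms: dict
    tubes: list
    truth: pd.DataFrame
    scheme: TiltScheme
    ctf: CTFProfile

    def particle_mask(self, box: int) -> FourierMask:
        lo = -self.manifest["scheme"]["tilt_max_deg"]
        wedge = binary_wedge((box,) * 3, lo, -lo)
        return composite_particle_mask(
            wedge, self.ctf, self.scheme, self.manifest["voxel_size_A"]
        )


def make_fixture(
    preset_name: str,
    seed: int,
    out_dir: str | Path,
    overwrite: bool = False,
    snr: float | None = None,
    arch_tilt_deg: float | None = None,
    jitter_A: float | None = None,
    jitter_deg: float | None = None,
) -> dict:
    """Write a self-contained fixture bundle the pipeline can consume.

    Bundle contents: one MRC tomogram + .tlt file per simulated tomogram,
    a tube-trace YAML, the ground-truth particle table, and a YAML manifest.
    """
    if preset_name not in PRESETS:
        raise ValidationError(f"unknown preset {preset_name!r}; choose from {sorted(PRESETS)}")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise ValidationError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    p = PRESETS[preset_name]
    vx = p["voxel_size_A"]
    lattice = dict(DEFAULT_LATTICE)
    if arch_tilt_deg is not None:
        lattice["arch_tilt_deg"] = float(arch_tilt_deg)
    if jitter_A is not None:
        lattice["jitter_A"] = float(jitter_A)
    if jitter_deg is not None:
        lattice["jitter_deg"] = float(jitter_deg)
    snr_val = float(p["snr"] if snr is None else snr)
    motifs = [render_motif(vx, v) for v in p["variants"]]
    scheme = dose_symmetric_scheme(**{
        "tilt_max_deg": DEFAULT_SCHEME["tilt_max_deg"],
        "n_tilts": DEFAULT_SCHEME["n_tilts"],
        "total_dose_eA2": DEFAULT_SCHEME["total_dose_eA2"],
    })
    ctf = ctf_amplitude_profile(**DEFAULT_OPTICS)

    tubes: list[TubeModel] = []
    truth_tables = []
    manifest_tomos = []
    tube_id = 1
    next_pid = 0
    for tomo_id, (shape, tube_specs) in enumerate(p["tomograms"]):
        truth_vol = np.zeros(shape, dtype=np.float64)
        for (cxz, y0, length) in tube_specs:
            tube = _straight_tube(cxz, y0, length, p["radius_A"], tomo_id, tube_id)
            spec = LatticeSpec(
                tube=tube,
                axial_rise_A=lattice["axial_rise_A"],
                units_per_turn=p["units_per_turn"],
                arch_tilt_deg=lattice["arch_tilt_deg"],
                unit_density=motifs if len(motifs) > 1 else motifs[0],
                voxel_size_A=vx,
                volume_shape=shape,
                jitter_A=lattice["jitter_A"],
                jitter_deg=lattice["jitter_deg"],
                seed=int(np.random.default_rng([seed, tube_id]).integers(2**31)),
                arch_height_A=lattice["arch_height_A"],
            )
            tbl, vol = build_ground_truth(spec)
            tbl["particle_id"] = np.arange(next_pid, next_pid + len(tbl))
            next_pid += len(tbl)
            truth_vol += vol.data
            tubes.append(tube)
            truth_tables.append(tbl)
            tube_id += 1
        clean = DensityVolume(truth_vol.astype(np.float32), vx)
        wedge = binary_wedge(shape, -scheme.tilt_range_deg[1], scheme.tilt_range_deg[1])
        mask = composite_particle_mask(wedge, ctf, scheme, vx)
        rng = np.random.default_rng([seed, 1000 + tomo_id])
        filtered = apply_wedge_to_volume(clean, mask)
        tomo_truth = pd.concat(
            [t for t in truth_tables if (t["tomo_id"] == tomo_id).all()],
            ignore_index=True,
        )
        sig_var = crop_signal_variance(filtered, tomo_truth, p["boxsize"])
        tomo = apply_wedge_to_volume(
            clean, mask, NoiseModel(snr_val, seed=seed), rng=rng, signal_var=sig_var
        )
        mrc_path = out / f"tomo_{tomo_id}.mrc"
        io_formats.write_volume(tomo, mrc_path)
        tlt_path = out / f"tomo_{tomo_id}.tlt"
        io_formats.write_tilt_file(scheme.angles_deg, tlt_path)
        manifest_tomos.append(
            {"tomo_id": tomo_id, "mrc": mrc_path.name, "tlt": tlt_path.name,
             "shape_zyx": list(shape)}
        )

    truth = pd.concat(truth_tables, ignore_index=True)
    io_formats.write_particle_table(truth, out / "truth_particles.tsv")
    tubes_doc = [
        {"tomo_id": t.tomo_id, "tube_id": t.tube_id, "radius_A": float(t.radius_A),
         "centerline": [[float(v) for v in row] for row in t.centerline]}
        for t in tubes
    ]
    (out / "tubes.yaml").write_text(yaml.safe_dump(tubes_doc, sort_keys=False))
    manifest = {
        "preset": preset_name,
        "seed": int(seed),
        "voxel_size_A": vx,
        "boxsize": p["boxsize"],
        "snr": snr_val,
        "spacing_A": 44.0,
        "radius_A": p["radius_A"],
        "optics": DEFAULT_OPTICS,
        "scheme": DEFAULT_SCHEME,
        "lattice": {**lattice, "units_per_turn": p["units_per_turn"],
                    "variants": p["variants"]},
        "tomograms": manifest_tomos,
        "tubes": "tubes.yaml",
        "truth": "truth_particles.tsv",
    }
    io_formats.save_config(manifest, out / "manifest.yaml")
    return manifest


def load_fixture(fixture_dir: str | Path) -> FixtureBundle:
    root = Path(fixture_dir)
    manifest = io_formats.load_config(root / "manifest.yaml")
    tomograms = {
        t["tomo_id"]: io_formats.read_volume(root / t["mrc"])
        for t in manifest["tomograms"]
    }
    tubes = [
        TubeModel(np.asarray(doc["centerline"], dtype=float), doc["radius_A"],
                  tomo_id=doc["tomo_id"], tube_id=doc["tube_id"])
        for doc in yaml.safe_load((root / manifest["tubes"]).read_text())
    ]
    truth = io_formats.read_particle_table(root / manifest["truth"])
    scheme = dose_symmetric_scheme(
        manifest["scheme"]["tilt_max_deg"],
        manifest["scheme"]["n_tilts"],
        manifest["scheme"]["total_dose_eA2"],
    )
    ctf = ctf_amplitude_profile(**manifest["optics"])
    return FixtureBundle(manifest, root, tomograms, tubes, truth, scheme, ctf)
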