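"""Constrained cross-correlation alignment and wedge-weighted averaging.

The correlation statistic follows the TOM/AV3 lineage: the reference is
multiplied by the particle's Fourier sampling mask before correlation, so
only mutually measured frequencies contribute; both volumes are normalized to
zero mean and unit variance under the real-space mask; the peak of the
resulting normalized correlation map over the allowed shift radius is refined
to subvoxel precision by parabolic interpolation.

Averaging is wedge-compensated: masked particles are summed in Fourier space
and divided by the sum of their rotated masks wherever the accumulated weight
exceeds a floor; summation order is fixed (particle_id ascending) for
bit-reproducibility.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .errors import (
    DegenerateInputError,
    ExtractionError,
    PipelineError,
    ValidationError,
)
from .fourier_filters import FourierMask
from .geometry import (
    EulerTriplet,
    euler_to_matrix,
    invert_pose,
    matrix_to_euler,
    rotate_array,
)
from .io_formats import DensityVolume

logger = logging.getLogger(__name__)

EULER_COLS = ["phi", "theta", "psi"]
SHIFT_COLS = ["shift_x", "shift_y", "shift_z"]
POS_COLS = ["pos_x", "pos_y", "pos_z"]


# --------------------------------------------------------------------------
# Real-space masks
# --------------------------------------------------------------------------


def soft_sphere_mask(box: int, radius_vox: float | None = None,
                     edge_vox: float = 3.0, center_xyz_vox=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Soft-edged spherical mask: 1 inside, raised-cosine edge.

    ``center_xyz_vox`` offsets the sphere from the box center (used to focus
    the correlation on the particle's own coat unit rather than the whole
    neighborhood)."""
    if radius_vox is None:
        radius_vox = 0.4 * box
    cx, cy, cz = center_xyz_vox
    zz, yy, xx = np.meshgrid(*[np.arange(box) - box // 2] * 3, indexing="ij")
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2)
    if edge_vox <= 0:
        return (r <= radius_vox).astype(np.float32)
    t = np.clip((r - radius_vox) / edge_vox, 0.0, 1.0)
    return (0.5 * (1 + np.cos(np.pi * t))).astype(np.float32)


def soft_cylinder_mask(box: int, radius_vox: float, z_lo_vox: float,
                       z_hi_vox: float, edge_vox: float = 3.0,
                       center_xy_vox=(0.0, 0.0)) -> np.ndarray:
    """Soft cylinder along z (the membrane-normal axis of the reference frame),
    spanning z in [z_lo, z_hi] voxels relative to the box center; the lateral
    center may be offset (e.g. onto the reference's arch)."""
    cx, cy = center_xy_vox
    zz, yy, xx = np.meshgrid(*[np.arange(box) - box // 2] * 3, indexing="ij")
    rho = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    t_r = np.clip((rho - radius_vox) / max(edge_vox, 1e-6), 0.0, 1.0)
    w = 0.5 * (1 + np.cos(np.pi * t_r))
    t_lo = np.clip((z_lo_vox - zz) / max(edge_vox, 1e-6), 0.0, 1.0)
    t_hi = np.clip((zz - z_hi_vox) / max(edge_vox, 1e-6), 0.0, 1.0)
    w = w * 0.5 * (1 + np.cos(np.pi * t_lo)) * 0.5 * (1 + np.cos(np.pi * t_hi))
    return w.astype(np.float32)


def normalize_under_mask(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero mean, unit variance under ``mask`` (used as weights)."""
    msum = float(mask.sum())
    if msum <= 0:
        raise ValidationError("real mask is empty")
    mu = float((data * mask).sum()) / msum
    var = float((mask * (data - mu) ** 2).sum()) / msum
    if var < 1e-20:
        raise DegenerateInputError("zero variance under the real-space mask")
    return (data - mu) / np.sqrt(var)


# --------------------------------------------------------------------------
# Angular grids and refinement schedules
# --------------------------------------------------------------------------


def _cone_direction(theta_deg: float, az_deg: float) -> np.ndarray:
    """Rotation tilting the z-axis by theta toward azimuth az, without twist."""
    t, a = np.deg2rad(theta_deg), np.deg2rad(az_deg)
    rz = lambda g: np.array([[np.cos(g), -np.sin(g), 0],
                             [np.sin(g), np.cos(g), 0], [0, 0, 1.0]])
    rx = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)],
                   [0, np.sin(t), np.cos(t)]])
    return rz(a) @ rx @ rz(-a)


@dataclasses.dataclass
class AngularGrid:
    """Cone sampling of z-axis directions crossed with in-plane steps.

    Directions sample the spherical cap of half-angle ``cone_half_angle_deg``
    approximately uniformly (rings every ``cone_step_deg`` with
    round(360 sin(theta)/step) azimuths); each direction is combined with
    in-plane rotations in [-inplane_range_deg, +inplane_range_deg].  The
    identity offset is always present and always first (the tie-break order).
    """

    cone_half_angle_deg: float
    cone_step_deg: float
    inplane_range_deg: float
    inplane_step_deg: float

    def __post_init__(self) -> None:
        if self.cone_half_angle_deg < 0 or self.inplane_range_deg < 0:
            raise ValidationError("angular ranges must be non-negative")
        if (self.cone_half_angle_deg > 0 and self.cone_step_deg <= 0) or (
            self.inplane_range_deg > 0 and self.inplane_step_deg <= 0
        ):
            raise ValidationError("angular steps must be positive")

    def offsets(self) -> list[np.ndarray]:
        """Materialized rotation-matrix offsets, identity first."""
        psis = [0.0]
        if self.inplane_range_deg > 0:
            n = int(np.floor(self.inplane_range_deg / self.inplane_step_deg + 1e-9))
            for k in range(1, n + 1):
                psis += [k * self.inplane_step_deg, -k * self.inplane_step_deg]
        dirs = [np.eye(3)]
        if self.cone_half_angle_deg > 0:
            thetas = np.arange(
                self.cone_step_deg, self.cone_half_angle_deg + 1e-9, self.cone_step_deg
            )
            for th in thetas:
                n_az = max(1, int(round(360.0 * np.sin(np.deg2rad(th))
                                        / self.cone_step_deg)))
                for j in range(n_az):
                    dirs.append(_cone_direction(th, 360.0 * j / n_az))
        rz = lambda g: np.array([[np.cos(g), -np.sin(g), 0],
                                 [np.sin(g), np.cos(g), 0], [0, 0, 1.0]])
        out = []
        for d in dirs:
            for psi in psis:
                out.append(d @ rz(np.deg2rad(psi)) if psi else d.copy())
        return out


@dataclasses.dataclass
class IterationSpec:
    """One refinement iteration.

    ``cc_mask`` selects the real-space correlation mask: ``"sphere"`` (a soft
    sphere over the whole neighborhood; robust, used early) or ``"protein"``
    (a soft cylinder over the coat-protein layer only, excluding the membrane
    and neighboring units; accurate, used late — the static membrane otherwise
    pulls poses toward the ideal lattice).  The protein cylinder is placed
    laterally on the reference's own arch (its apex peak), so it works in the
    seeding gauge where the self-built reference's arch sits at an arbitrary
    lateral offset.
    """

    grid: AngularGrid
    max_shift_vox: float
    lowpass_A: float | None = None
    cc_mask: str = "sphere"
    local_refine_rounds: int = 2
    protein_mask_radius_A: float = 40.0
    protein_mask_z_A: tuple = (48.0, 132.0)

    def real_mask(self, box: int, voxel_size_A: float,
                  reference: DensityVolume | None = None) -> np.ndarray:
        if self.cc_mask == "sphere":
            return soft_sphere_mask(box)
        if self.cc_mask == "protein":
            center = (0.0, 0.0)
            if reference is not None:
                center = find_apex_lateral(reference)
            return soft_cylinder_mask(
                box,
                radius_vox=self.protein_mask_radius_A / voxel_size_A,
                z_lo_vox=self.protein_mask_z_A[0] / voxel_size_A,
                z_hi_vox=min(self.protein_mask_z_A[1] / voxel_size_A, box / 2 - 2),
                edge_vox=1.0,
                center_xy_vox=center,
            )
        raise ValidationError(f"unknown cc_mask kind {self.cc_mask!r}")


@dataclasses.dataclass
class RefinementSchedule:
    """Ordered refinement iterations; angular steps must not increase and the
    low-pass cutoff must not move toward lower resolution."""

    iterations: list

    def __post_init__(self) -> None:
        if not self.iterations:
            raise ValidationError("schedule must contain at least one iteration")
        steps = [it.grid.cone_step_deg for it in self.iterations]
        if any(b > a + 1e-9 for a, b in zip(steps, steps[1:])):
            raise ValidationError("angular steps must be non-increasing")
        lps = [it.lowpass_A for it in self.iterations if it.lowpass_A is not None]
        if any(b > a + 1e-9 for a, b in zip(lps, lps[1:])):
            raise ValidationError("low-pass cutoff must move toward higher resolution")

    def __iter__(self):
        return iter(self.iterations)

    def __len__(self):
        return len(self.iterations)


# --------------------------------------------------------------------------
# Constrained cross-correlation
# --------------------------------------------------------------------------


def _shift_ball(box: int, max_shift: float) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(box) - box // 2] * 3, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= max_shift**2 + 1e-9


def _parabolic_1d(vm: float, v0: float, vp: float) -> tuple[float, float]:
    denom = vm - 2 * v0 + vp
    if abs(denom) < 1e-12 or denom > 0:
        return 0.0, 0.0
    off = 0.5 * (vm - vp) / denom
    off = float(np.clip(off, -0.5, 0.5))
    gain = -0.25 * (vm - vp) * off
    return off, float(gain)


def _peak_from_map(cc: np.ndarray, ball: np.ndarray, subvoxel: bool,
                   line_dir: np.ndarray | None = None):
    """Peak (value, shift_xyz) of a zero-shift-centered cc map.

    ``line_dir`` restricts the search to a line through the origin (used by
    the membrane-normal bootstrap stage)."""
    box = cc.shape[0]
    c = box // 2
    if line_dir is not None:
        from scipy import ndimage
        n = line_dir / np.linalg.norm(line_dir)
        radius = 0
        while radius + 1 <= c and ball[c, c, min(c + radius + 1, box - 1)]:
            radius += 1
        samples = np.arange(-radius, radius + 1, 0.5)
        pts = np.stack([c + samples * n[2], c + samples * n[1], c + samples * n[0]])
        vals = ndimage.map_coordinates(cc, pts, order=1, prefilter=False)
        i = int(np.argmax(vals))
        t = samples[i]
        if subvoxel and 0 < i < len(vals) - 1:
            off, gain = _parabolic_1d(vals[i - 1], vals[i], vals[i + 1])
            t = t + 0.5 * off
            return float(np.clip(vals[i] + gain, -1, 1)), t * n
        return float(np.clip(vals[i], -1, 1)), t * n
    masked = np.where(ball, cc, -np.inf)
    idx = np.unravel_index(int(np.argmax(masked)), cc.shape)
    val = float(cc[idx])
    shift = np.array([idx[2] - c, idx[1] - c, idx[0] - c], dtype=float)  # xyz
    if subvoxel:
        for ax, xyz in ((2, 0), (1, 1), (0, 2)):
            i = idx[ax]
            if 0 < i < box - 1:
                lo = list(idx); hi = list(idx)
                lo[ax] -= 1; hi[ax] += 1
                off, gain = _parabolic_1d(
                    float(cc[tuple(lo)]), float(cc[idx]), float(cc[tuple(hi)])
                )
                shift[xyz] += off
                val += gain
    return float(np.clip(val, -1.0, 1.0)), shift


def _cc_map(sub_prepped_f: np.ndarray, ref_masked: np.ndarray,
            real_mask: np.ndarray, msum: float, box: int) -> np.ndarray:
    """Normalized correlation map (zero shift at the box center)."""
    refn = normalize_under_mask(ref_masked, real_mask) * np.sqrt(real_mask)
    fr = sfft.rfftn(refn)
    cc = sfft.irfftn(sub_prepped_f * np.conj(fr), s=(box,) * 3) / msum
    return sfft.fftshift(cc)


def _prep_subtomo(data: np.ndarray, real_mask: np.ndarray) -> np.ndarray:
    subn = normalize_under_mask(data, real_mask) * np.sqrt(real_mask)
    return sfft.rfftn(subn)


def constrained_cc(
    subtomo: DensityVolume,
    reference: DensityVolume,
    particle_mask: FourierMask | None,
    real_mask: np.ndarray | None = None,
    max_shift_vox: float | None = None,
    subvoxel: bool = True,
) -> tuple[float, np.ndarray]:
    """Missing-wedge-constrained normalized cross-correlation.

    Returns (cc_peak, shift_xyz): the peak of the normalized correlation map
    within ``max_shift_vox`` of zero shift, and the translation of the
    reference that maximizes it.  ``particle_mask`` (the particle's composite
    Fourier mask) is applied to the reference before correlation.
    """
    a = subtomo.data.astype(np.float64)
    b = reference.data.astype(np.float64)
    if a.shape != b.shape or a.shape[0] != a.shape[1] or a.shape[0] != a.shape[2]:
        raise ValidationError("subtomogram and reference must be equal cubic volumes")
    box = a.shape[0]
    if real_mask is None:
        real_mask = np.ones(a.shape, dtype=np.float32)
    if max_shift_vox is None:
        max_shift_vox = box / 4.0
    if particle_mask is not None:
        b = sfft.irfftn(
            sfft.rfftn(b) * particle_mask.rfft_weights(), s=b.shape
        )
    fa = _prep_subtomo(a, real_mask)
    cc = _cc_map(fa, b, real_mask, float(real_mask.sum()), box)
    ball = _shift_ball(box, max_shift_vox)
    return _peak_from_map(cc, ball, subvoxel)


# --------------------------------------------------------------------------
# Per-particle grid-search alignment (contract form)
# --------------------------------------------------------------------------


def align_particle(
    record,
    subtomo: DensityVolume,
    reference: DensityVolume,
    grid: AngularGrid,
    particle_mask: FourierMask | None,
    real_mask: np.ndarray | None = None,
    max_shift_vox: float = 6.0,
    bandpass_mask: FourierMask | None = None,
):
    """Exhaustive search over the angular grid maximizing constrained CC.

    The record's Euler angles are composed with the best offset and its shift
    columns set to the recovered translation (world frame, x/y/z voxels).
    Ties break to the first-encountered maximum in grid order.
    """
    rec = record.copy()
    box = subtomo.data.shape[0]
    if real_mask is None:
        real_mask = np.ones((box,) * 3, dtype=np.float32)
    r_cur = euler_to_matrix(EulerTriplet(rec["phi"], rec["theta"], rec["psi"]))
    sub = subtomo.data.astype(np.float64)
    if bandpass_mask is not None:
        sub = sfft.irfftn(sfft.rfftn(sub) * bandpass_mask.rfft_weights(), s=sub.shape)
    wr = None
    if particle_mask is not None:
        w = particle_mask.weights
        if bandpass_mask is not None:
            w = w * bandpass_mask.weights
        wr = FourierMask(w, particle_mask.tilt_range_deg).rfft_weights()
    fa = _prep_subtomo(sub, real_mask)
    msum = float(real_mask.sum())
    ball = _shift_ball(box, max_shift_vox)
    best = (-np.inf, None, None)
    for off in grid.offsets():
        r_cand = r_cur @ off
        ref_rot = rotate_array(reference.data, r_cand).astype(np.float64)
        if wr is not None:
            ref_rot = sfft.irfftn(sfft.rfftn(ref_rot) * wr, s=ref_rot.shape)
        try:
            cc = _cc_map(fa, ref_rot, real_mask, msum, box)
        except DegenerateInputError:
            continue
        val, shift = _peak_from_map(cc, ball, subvoxel=True)
        if val > best[0]:
            best = (val, r_cand, shift)
    if best[1] is None:
        rec["cc_score"] = np.nan
        return rec
    e = matrix_to_euler(best[1])
    rec["phi"], rec["theta"], rec["psi"] = e.as_tuple()
    rec["shift_x"], rec["shift_y"], rec["shift_z"] = best[2]
    rec["cc_score"] = best[0]
    return rec


# --------------------------------------------------------------------------
# Batch alignment (rotates each subtomogram into the reference frame once and
# shares the rotated references across particles; equivalent to
# align_particle up to interpolation order)
# --------------------------------------------------------------------------


def _local_offsets(step_deg: float) -> list[np.ndarray]:
    """Six single-axis perturbations of the given step (cone x/y, in-plane)."""
    out = []
    for axis in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
        for sign in (1.0, -1.0):
            a = np.deg2rad(sign * step_deg)
            x, y, z = axis
            k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]], dtype=float)
            out.append(np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k))
    return out


def align_table(
    table: pd.DataFrame,
    source,
    reference: DensityVolume,
    grid: AngularGrid,
    real_mask: np.ndarray,
    max_shift_vox: float,
    bandpass_mask: FourierMask | None = None,
    line_search_normal: bool = False,
    local_refine_rounds: int = 2,
) -> pd.DataFrame:
    """Align every particle in ``table`` against ``reference``.

    ``source`` provides ``get(record) -> (DensityVolume, frac_xyz)`` and
    ``mask(record) -> FourierMask``.  With ``line_search_normal`` the angular
    grid is ignored and only a translation along the particle z-axis (the
    membrane normal) is searched — the ab initio membrane-layer stage.

    After the exhaustive grid search the best orientation is polished by
    ``local_refine_rounds`` rounds of single-axis perturbations with halved
    step — the angular analogue of the subvoxel parabolic shift fit, removing
    grid-quantization error without changing the search resolution.
    """
    box = reference.data.shape[0]
    msum = float(real_mask.sum())
    ball = _shift_ball(box, max_shift_vox)
    ref = reference.data.astype(np.float64)
    if bandpass_mask is not None:
        bw = bandpass_mask.rfft_weights()
        ref = sfft.irfftn(sfft.rfftn(ref) * bw, s=ref.shape)
    offs = [np.eye(3)] if line_search_normal else grid.offsets()
    f_ref = [sfft.rfftn(rotate_array(ref, off)) for off in offs]
    line_dir = np.array([0.0, 0.0, 1.0]) if line_search_normal else None
    out = table.copy()
    for idx in out.index:
        rec = out.loc[idx]
        try:
            vol, _frac = source.get(rec)
        except ExtractionError:
            out.loc[idx, "cc_score"] = np.nan
            continue
        r_cur = euler_to_matrix(EulerTriplet(rec["phi"], rec["theta"], rec["psi"]))
        sub = rotate_array(vol.data.astype(np.float64), r_cur.T)
        if bandpass_mask is not None:
            sub = sfft.irfftn(sfft.rfftn(sub) * bw, s=sub.shape)
        pm = source.mask(rec)
        wrot = None
        if pm is not None:
            w = np.clip(rotate_array(pm.weights, r_cur.T, cval=0.0), 0.0, 1.0)
            full = np.fft.ifftshift(w)
            wrot = np.ascontiguousarray(full[..., : full.shape[-1] // 2 + 1])
        try:
            fa = _prep_subtomo(sub, real_mask)
        except DegenerateInputError:
            out.loc[idx, "cc_score"] = np.nan
            continue

        def evaluate(fr):
            g = sfft.irfftn(fr * wrot, s=sub.shape) if wrot is not None else \
                sfft.irfftn(fr, s=sub.shape)
            cc = _cc_map(fa, g, real_mask, msum, box)
            return _peak_from_map(cc, ball, subvoxel=True, line_dir=line_dir)

        best = (-np.inf, None, None)
        for off, fr in zip(offs, f_ref):
            try:
                val, shift_ref = evaluate(fr)
            except DegenerateInputError:
                continue
            if val > best[0]:
                best = (val, off, shift_ref)
        if best[1] is None:
            out.loc[idx, "cc_score"] = np.nan
            continue
        if not line_search_normal and local_refine_rounds > 0 and grid.cone_step_deg > 0:
            step = grid.cone_step_deg
            for _ in range(local_refine_rounds):
                step *= 0.5
                for _sweep in range(2):
                    improved = False
                    for d in _local_offsets(step):
                        cand = best[1] @ d
                        try:
                            val, shift_ref = evaluate(sfft.rfftn(rotate_array(ref, cand)))
                        except DegenerateInputError:
                            continue
                        if val > best[0]:
                            best = (val, cand, shift_ref)
                            improved = True
                    if not improved:
                        break
        r_new = r_cur @ best[1]
        t_world = r_cur @ np.asarray(best[2], dtype=float)
        e = matrix_to_euler(r_new)
        out.loc[idx, EULER_COLS] = e.as_tuple()
        out.loc[idx, SHIFT_COLS] = t_world
        out.loc[idx, "cc_score"] = best[0]
    return out


def fold_shifts(table: pd.DataFrame) -> pd.DataFrame:
    """Move per-iteration shifts into positions (and zero the shift columns)."""
    out = table.copy()
    out[POS_COLS] = out[POS_COLS].to_numpy() + out[SHIFT_COLS].to_numpy()
    out[SHIFT_COLS] = 0.0
    return out


# --------------------------------------------------------------------------
# Wedge-weighted averaging
# --------------------------------------------------------------------------


@dataclasses.dataclass
class AverageResult:
    mean_map: DensityVolume
    wedge_sum: np.ndarray  # DC-centered accumulated Fourier weights
    n_particles: int
    per_particle_cc: list


def average_particles(
    table: pd.DataFrame,
    source,
    real_mask: np.ndarray | None = None,
    wedge_floor_rel: float = 0.1,
    normalize_output: bool = True,
) -> AverageResult:
    """Wedge-compensated average of the table's particles.

    Every subtomogram is inverse-transformed to the reference frame; the
    Fourier-space sum of the (already mask-shaped) particles is divided by the
    sum of their rotated masks wherever that sum exceeds
    ``wedge_floor_rel * n_particles``.  Summation runs in particle_id order.
    """
    if len(table) == 0:
        raise ValidationError("cannot average an empty particle table")
    order = table.sort_values("particle_id").index
    f_sum = None
    w_sum = None
    n = 0
    n_skipped = 0
    for idx in order:
        rec = table.loc[idx]
        try:
            vol, frac = source.get(rec)
        except ExtractionError:
            n_skipped += 1
            continue
        box = vol.data.shape[0]
        r = euler_to_matrix(EulerTriplet(rec["phi"], rec["theta"], rec["psi"]))
        t = np.array([rec["shift_x"], rec["shift_y"], rec["shift_z"]]) + frac
        rinv, tinv = invert_pose(r, t)
        al = rotate_array(vol.data.astype(np.float64), rinv, tinv)
        pm = source.mask(rec)
        w = np.ones((box,) * 3, dtype=np.float64) if pm is None else np.clip(
            rotate_array(pm.weights.astype(np.float64), rinv, cval=0.0), 0.0, 1.0
        )
        if f_sum is None:
            f_sum = np.zeros((box,) * 3, dtype=np.complex128)
            w_sum = np.zeros((box,) * 3, dtype=np.float64)
        f_sum += np.fft.fftn(al)
        w_sum += w
        n += 1
    if n_skipped:
        logger.info("average_particles: skipped %d out-of-bounds particles", n_skipped)
    if f_sum is None:
        raise ValidationError("no particle could be extracted for averaging")
    w_unshift = np.fft.ifftshift(w_sum)
    floor = wedge_floor_rel * n
    keep = w_unshift >= floor
    f_avg = np.where(keep, f_sum / np.maximum(w_unshift, 1e-12), 0.0)
    mean = np.fft.ifftn(f_avg).real.astype(np.float32)
    if normalize_output:
        m = real_mask if real_mask is not None else np.ones_like(mean)
        mean = normalize_under_mask(mean.astype(np.float64), m).astype(np.float32)
    vx = vol.voxel_size_A
    return AverageResult(
        DensityVolume(mean, vx), w_sum, n, list(table.loc[order, "cc_score"])
    )


# --------------------------------------------------------------------------
# Subtomogram sources
# --------------------------------------------------------------------------


class TomogramSource:
    """Crops subtomograms out of reconstructed tomograms on demand.

    ``particle_mask`` may be a single composite Fourier mask (shared optics)
    or a dict keyed by tomo_id.
    """

    def __init__(self, tomograms: dict, box: int, particle_mask):
        self.tomograms = tomograms
        self.box = int(box)
        self.particle_mask = particle_mask

    def get(self, record):
        from .simulator import extract_crop

        tomo = self.tomograms[int(record["tomo_id"])]
        pos = np.array([record["pos_x"], record["pos_y"], record["pos_z"]], dtype=float)
        crop = extract_crop(tomo, pos, self.box)
        frac = pos - np.round(pos)
        return crop, frac

    def mask(self, record):
        if isinstance(self.particle_mask, dict):
            return self.particle_mask[int(record["tomo_id"])]
        return self.particle_mask


class VolumeSource:
    """Serves pre-simulated per-particle volumes (positions are box-centered)."""

    def __init__(self, volumes: dict, particle_mask):
        self.volumes = volumes
        self.particle_mask = particle_mask

    def get(self, record):
        return self.volumes[int(record["particle_id"])], np.zeros(3)

    def mask(self, record):
        if isinstance(self.particle_mask, dict):
            return self.particle_mask[int(record["particle_id"])]
        return self.particle_mask


# --------------------------------------------------------------------------
# Ab initio reference bootstrap
# --------------------------------------------------------------------------


def bootstrap_reference(
    seed_table: pd.DataFrame,
    source,
    voxel_size_A: float,
    box: int,
    subset_fraction: float = 0.5,
    angular_steps=(8.0, 7.0, 6.0, 5.0, 4.0),
    lowpass_A=40.0,
    max_shift_vox: float = 7.0,
    seed: int = 0,
):
    """Three-stage ab initio reference from membrane-normal seed orientations.

    Stage 1 averages the seeds at their initial orientations; stage 2 aligns
    each particle translationally along its membrane normal only (locking onto
    the bilayer/protein density layers); stage 3 iteratively refines a subset
    with a cone + in-plane search whose increment shrinks across iterations
    (8° to 4° by default) under a 40-Å low-pass (a per-iteration low-pass
    schedule may be given instead).

    Returns (reference, updated_table, info).
    """
    from .fourier_filters import bandpass as make_bandpass

    if len(seed_table) < 10:
        logger.warning("bootstrap on only %d particles", len(seed_table))
    cyl = soft_cylinder_mask(
        box,
        radius_vox=0.42 * box,
        z_lo_vox=-36.0 / voxel_size_A,
        z_hi_vox=min(box / 2.0 - 2.0, 140.0 / voxel_size_A),
    )
    lowpasses = (
        [float(lowpass_A)] * len(angular_steps)
        if np.isscalar(lowpass_A)
        else [float(v) for v in lowpass_A]
    )
    if len(lowpasses) != len(angular_steps):
        raise ValidationError("lowpass_A must be scalar or match angular_steps")
    bp = make_bandpass((box,) * 3, voxel_size_A, highcut_A=lowpasses[-1])
    table = seed_table.copy()
    stage1 = average_particles(table, source, real_mask=cyl)
    # stage 2: translational alignment along each particle's normal axis
    table = align_table(
        table, source, stage1.mean_map, AngularGrid(0, 0, 0, 0), cyl,
        max_shift_vox=max_shift_vox, bandpass_mask=bp, line_search_normal=True,
    )
    table = fold_shifts(table)
    stage2 = average_particles(table, source, real_mask=cyl)
    # stage 3: iterative cone + in-plane refinement on a subset.  The layer
    # average is laterally featureless, so iterating from it cannot break the
    # lattice-registration symmetry (every particle stays on its own noise
    # optimum); instead the first reference is nucleated from the single
    # best-scoring stage-2 subtomogram, which carries a real arch at a real
    # lattice position.
    rng = np.random.default_rng(seed)
    n_sub = max(min(len(table), 10), int(round(subset_fraction * len(table))))
    sub_idx = np.sort(rng.choice(table.index.to_numpy(), size=n_sub, replace=False))
    subset = table.loc[sub_idx]
    nucleus_idx = table["cc_score"].idxmax()
    ref = average_particles(
        table.loc[[nucleus_idx]], source, real_mask=cyl
    ).mean_map
    for step, lp in zip(angular_steps, lowpasses):
        grid = AngularGrid(step, step, step, step)
        bp_it = make_bandpass((box,) * 3, voxel_size_A, highcut_A=lp)
        # correlate over the protein layer around the reference's own arch:
        # the laterally featureless membrane carries no registration signal
        # and would otherwise dominate the correlation
        center = find_apex_lateral(ref)
        pmask = soft_cylinder_mask(
            box, radius_vox=40.0 / voxel_size_A,
            z_lo_vox=48.0 / voxel_size_A,
            z_hi_vox=min(132.0 / voxel_size_A, box / 2 - 2),
            edge_vox=1.0, center_xy_vox=center,
        )
        subset = align_table(
            subset, source, ref, grid, pmask,
            max_shift_vox=max_shift_vox, bandpass_mask=bp_it,
        )
        subset = fold_shifts(subset)
        subset = subset[subset["cc_score"].notna()]
        ref = average_particles(subset, source, real_mask=cyl).mean_map
    table.loc[subset.index] = subset
    info = {
        "n_seeds": int(len(seed_table)),
        "n_subset": int(n_sub),
        "angular_steps": list(angular_steps),
        "lowpass_A": lowpasses,
    }
    return ref, table, info


def find_apex_lateral(reference: DensityVolume, apex_lo_A: float = 72.0,
                      apex_hi_A: float = 130.0, smooth_A: float = 6.0):
    """Lateral (x, y) voxel offset of the strongest arch apex in a
    membrane-gauge average (bilayer mid-plane through the box center)."""
    from scipy import ndimage

    vx = reference.voxel_size_A
    data = reference.data.astype(np.float64)
    box = data.shape[0]
    zz, yy, xx = np.meshgrid(*[np.arange(box) - box // 2] * 3, indexing="ij")
    z_A = zz * vx
    band = (z_A >= apex_lo_A) & (z_A <= min(apex_hi_A, (box / 2.0 - 2.0) * vx))
    sm = ndimage.gaussian_filter(data, sigma=smooth_A / vx)
    pk = np.unravel_index(int(np.argmax(np.where(band, sm, -np.inf))), data.shape)
    return float(xx[pk]), float(yy[pk])


def estimate_arch_frame(
    reference: DensityVolume,
    z_lo_A: float = 36.0,
    z_hi_A: float = 130.0,
    apex_lo_A: float = 72.0,
    roi_radius_A: float = 60.0,
    smooth_A: float = 6.0,
    threshold_frac: float = 0.10,
    passes: int = 2,
):
    """Estimate the arch axis and centroid from a membrane-gauge average.

    Precondition: the map sits in the seeding gauge — bilayer mid-plane
    through the box center, protein layer toward +z.  The apex-band peak
    nearest the box axis seeds a lateral region of interest; within it, a
    mass-weighted line fit through the per-slice density centroids gives the
    arch axis (for a rigid leaning body whose cross-sections are centered on
    its own axis, those slice centroids fall exactly on the lean line).  The
    lateral ROI center is re-estimated once from the fit.

    Returns (axis_xyz_unit, centroid_offset_xyz_vox).
    """
    from scipy import ndimage

    vx = reference.voxel_size_A
    data = reference.data.astype(np.float64)
    box = data.shape[0]
    zz, yy, xx = np.meshgrid(*[np.arange(box) - box // 2] * 3, indexing="ij")
    z_A = zz * vx
    z_hi = min(z_hi_A, (box / 2.0 - 2.0) * vx)
    band = (z_A >= z_lo_A) & (z_A <= z_hi)
    sm = ndimage.gaussian_filter(data, sigma=smooth_A / vx)
    # seed the region of interest on one arch apex: local maxima in the
    # apex-height band, preferring the arch nearest the box axis (any lattice
    # arch is an equivalent gauge anchor; the nearest is unambiguous)
    apex_band = (z_A >= apex_lo_A) & (z_A <= z_hi)
    local_max = sm == ndimage.maximum_filter(sm, size=3)
    cand = apex_band & local_max & (sm > 0.5 * float(np.where(apex_band, sm, -np.inf).max()))
    if not cand.any():
        cand = apex_band
    lat = np.where(cand, xx**2 + yy**2, np.inf)
    pk = np.unravel_index(int(np.argmin(lat)), data.shape)
    pk_val = float(sm[pk])
    if not np.isfinite(pk_val) or pk_val <= 0:
        raise DegenerateInputError("no protein-layer density above the membrane")
    x0, y0 = float(xx[pk]), float(yy[pk])
    zs = np.arange(box) - box // 2
    axis = np.array([0.0, 0.0, 1.0])
    w = None
    for _ in range(max(passes, 1)):
        roi = (xx - x0) ** 2 + (yy - y0) ** 2 <= (roi_radius_A / vx) ** 2
        w = np.clip(sm - threshold_frac * pk_val, 0.0, None) * band * roi
        mz = w.sum(axis=(1, 2))
        if mz.max() <= 0:
            raise DegenerateInputError("no density in recentering region")
        good = mz > 0.10 * mz.max()
        if good.sum() < 3:
            raise DegenerateInputError("too few slices for the axis fit")
        cx = (w * xx).sum(axis=(1, 2))[good] / mz[good]
        cy = (w * yy).sum(axis=(1, 2))[good] / mz[good]
        zg, wg = zs[good].astype(float), mz[good]
        fit_x = np.polyfit(zg, cx, 1, w=np.sqrt(wg))
        fit_y = np.polyfit(zg, cy, 1, w=np.sqrt(wg))
        axis = np.array([fit_x[0], fit_y[0], 1.0])
        axis = axis / np.linalg.norm(axis)
        zbar = float((wg * zg).sum() / wg.sum())
        x0, y0 = float(np.polyval(fit_x, zbar)), float(np.polyval(fit_y, zbar))
    wsum = w.sum()
    com = np.array([(w * xx).sum(), (w * yy).sum(), (w * zz).sum()]) / wsum
    return axis, com


def recenter_reference(reference: DensityVolume, table: pd.DataFrame | None = None,
                       **kwargs):
    """Rotate and shift the reference so the arch axis is +z and the arch
    centroid sits at the box center; apply the same gauge change to the table.

    Expects a membrane-gauge average (see :func:`estimate_arch_frame`).  The
    self-built arch may sit anywhere within a lattice cell of the box axis —
    including near the box edge, where the axis fit is unreliable — so the map
    is first rolled laterally (an exact integer translation) to put its apex
    on the axis, the frame is estimated there, and the roll is composed into
    the returned gauge.

    Returns (new_reference, new_table, gauge) where gauge = (R_g, shift_xyz).
    """
    from .geometry import align_vector_rotation, rotate_shift_volume

    x0, y0 = find_apex_lateral(reference, **{
        k: v for k, v in kwargs.items() if k in ("smooth_A",)
    })
    dx, dy = int(round(x0)), int(round(y0))
    rolled = reference
    if dx or dy:
        rolled = DensityVolume(
            np.roll(reference.data, shift=(-dy, -dx), axis=(1, 2)),
            reference.voxel_size_A, reference.origin_A,
        )
    axis, centroid = estimate_arch_frame(rolled, **kwargs)
    r_g = align_vector_rotation(axis, np.array([0.0, 0.0, 1.0]))
    s_roll = np.array([-dx, -dy, 0.0])
    s_g = -(r_g @ centroid) + r_g @ s_roll  # compose: roll first, then rotate/shift
    max_shift = reference.data.shape[0] / 4.0 - 1e-6
    s_g = np.clip(s_g, -max_shift, max_shift)
    new_ref = rotate_shift_volume(reference, r_g, s_g)
    new_table = apply_gauge(table, r_g, s_g) if table is not None else None
    return new_ref, new_table, (r_g, s_g)


def apply_gauge(table: pd.DataFrame, r_g: np.ndarray, s_g) -> pd.DataFrame:
    """Compose a reference-frame change (R_g, s_g) into every particle pose."""
    out = table.copy()
    s_g = np.asarray(s_g, dtype=float)
    for idx in out.index:
        rec = out.loc[idx]
        r = euler_to_matrix(EulerTriplet(rec["phi"], rec["theta"], rec["psi"]))
        r_new = r @ r_g.T
        e = matrix_to_euler(r_new)
        out.loc[idx, EULER_COLS] = e.as_tuple()
        out.loc[idx, POS_COLS] = (
            out.loc[idx, POS_COLS].to_numpy(dtype=float) - r_new @ s_g
        )
    return out


# --------------------------------------------------------------------------
# Iterative refinement with optional independent half-sets
# --------------------------------------------------------------------------


def run_refinement(
    table: pd.DataFrame,
    source,
    reference: DensityVolume,
    schedule: RefinementSchedule,
    voxel_size_A: float,
    halfsets: bool = False,
    dedup_distance_A: float = 55.0,
    real_mask: np.ndarray | None = None,
):
    """Iterate (align -> fold shifts -> duplicate removal -> re-average).

    With ``halfsets`` the table is split by tubule parity and the halves are
    refined fully independently (separate references after the split); the
    audit log records which reference every particle was aligned against.

    Returns (tables, averages, metrics, audit): per-group final tables and
    AverageResults, per-iteration metric dicts, and per-particle audit rows.
    The whole refinement runs in the seeding gauge; the arch-axis gauge is
    fixed afterwards with :func:`recenter_reference` on the final averages.
    """
    from .cleanup import remove_duplicates
    from .fourier_filters import bandpass as make_bandpass
    from .resolution import assign_halfsets

    box = reference.data.shape[0]
    if real_mask is None:
        real_mask = soft_sphere_mask(box)
    if halfsets:
        table = assign_halfsets(table)
        groups = {h: table[table["halfset"] == h].copy() for h in ("odd", "even")}
        groups = {h: t for h, t in groups.items() if len(t)}
    else:
        groups = {"all": table.copy()}
    refs = {g: reference for g in groups}
    averages: dict = {}
    metrics: list = []
    audit: list = []
    for i, it in enumerate(schedule):
        for g, t in list(groups.items()):
            if len(t) == 0:
                raise PipelineError(f"iteration {i}: no particles left in group {g!r}")
            ref_id = f"iter{i}:{g}"
            bp = None
            if it.lowpass_A is not None:
                bp = make_bandpass((box,) * 3, voxel_size_A, highcut_A=it.lowpass_A)
            cc_mask = it.real_mask(box, voxel_size_A, reference=refs[g])
            aligned = align_table(
                t, source, refs[g], it.grid, cc_mask,
                max_shift_vox=it.max_shift_vox, bandpass_mask=bp,
                local_refine_rounds=it.local_refine_rounds,
            )
            audit.extend(
                {"iteration": i, "group": g, "particle_id": int(p), "reference": ref_id}
                for p in aligned["particle_id"]
            )
            aligned = fold_shifts(aligned)
            n_flagged = int(aligned["cc_score"].isna().sum())
            if n_flagged:
                logger.info("iteration %d: dropping %d unalignable particles", i, n_flagged)
                aligned = aligned[aligned["cc_score"].notna()]
            deduped, report = remove_duplicates(aligned, dedup_distance_A, voxel_size_A)
            if len(deduped) == 0:
                raise PipelineError(f"iteration {i}: all particles removed in group {g!r}")
            avg = average_particles(deduped, source, real_mask=real_mask)
            groups[g] = deduped
            refs[g] = avg.mean_map
            averages[g] = avg
            metrics.append({
                "iteration": i,
                "group": g,
                "reference": ref_id,
                "n_aligned": int(len(aligned)),
                "n_after_dedup": int(len(deduped)),
                "mean_cc": float(np.nanmean(deduped["cc_score"].to_numpy())),
                "cone_step_deg": it.grid.cone_step_deg,
                "lowpass_A": it.lowpass_A,
            })
    return groups, averages, metrics, audit
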