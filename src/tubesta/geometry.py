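"""Rotation algebra, rigid volume resampling, and tube-surface seeding.

Euler convention (fixed for the whole package)
----------------------------------------------
``EulerTriplet(phi, theta, psi)`` in degrees composes **intrinsic ZXZ, active**:

    R = Rz(phi) @ Rx(theta) @ Rz(psi)

R maps reference-frame coordinates onto the particle frame, i.e. the columns
of R are the particle's x/y/z axes expressed in world coordinates.  Worked
example: (phi, theta, psi) = (90, 0, 0) maps the unit x-vector onto the unit
y-vector.

Box convention: rotations of an N-cube pivot about voxel (N/2, N/2, N/2)
(for even N this is the half-open box center used throughout cryo-EM).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .io_formats import DensityVolume, new_particle_table

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Euler triplets and rotation matrices
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class EulerTriplet:
    phi: float
    theta: float
    psi: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.phi, self.theta, self.psi)


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def euler_to_matrix(e: EulerTriplet | tuple[float, float, float]) -> np.ndarray:
    """Rotation matrix of an intrinsic ZXZ active Euler triplet (degrees)."""
    if not isinstance(e, EulerTriplet):
        e = EulerTriplet(*e)
    phi, theta, psi = np.deg2rad([e.phi, e.theta, e.psi])
    return _rz(phi) @ _rx(theta) @ _rz(psi)


def matrix_to_euler(R: np.ndarray) -> EulerTriplet:
    """Inverse of :func:`euler_to_matrix`; gimbal-locked inputs return psi=0."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-6:
        raise ValidationError("matrix_to_euler requires an orthonormal 3x3 matrix")
    if np.linalg.det(R) < 0:
        raise ValidationError("matrix_to_euler requires det(R) = +1")
    ct = float(np.clip(R[2, 2], -1.0, 1.0))
    theta = np.arccos(ct)
    if np.sin(theta) > 1e-8:
        phi = np.arctan2(R[0, 2], -R[1, 2])
        psi = np.arctan2(R[2, 0], R[2, 1])
    elif ct > 0:  # theta ~ 0: R = Rz(phi + psi)
        phi = np.arctan2(R[1, 0], R[0, 0])
        psi = 0.0
    else:  # theta ~ 180: R = Rz(phi - psi) . Rx(180)
        phi = np.arctan2(R[0, 1], R[0, 0])
        psi = 0.0
    return EulerTriplet(*np.rad2deg([phi, theta, psi]))


def rotation_geodesic_deg(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic angle in degrees between two rotations."""
    tr = np.clip((np.trace(Ra.T @ Rb) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.rad2deg(np.arccos(tr)))


def align_vector_rotation(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying unit vector ``v_from`` onto ``v_to``."""
    a = np.asarray(v_from, dtype=float)
    b = np.asarray(v_to, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(a @ b)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


# --------------------------------------------------------------------------
# Rigid resampling
# --------------------------------------------------------------------------

_PERM = np.eye(3)[::-1]  # (x,y,z) <-> (z,y,x) basis reversal


def rotate_array(
    data: np.ndarray,
    R: np.ndarray,
    shift_xyz=(0.0, 0.0, 0.0),
    cval: float | None = None,
) -> np.ndarray:
    """Actively rotate ``data`` by R about the box center, then shift.

    output(x) = input(R^-1 (x - c - shift) + c) with trilinear interpolation;
    out-of-bounds voxels are filled with ``cval`` (default: the input mean).
    Arrays are [z,y,x]; R and shift act on (x,y,z) coordinates.
    """
    data = np.asarray(data)
    n = data.shape[0]
    if data.shape != (n, n, n):
        raise ValidationError("rotate_array requires a cubic volume")
    c = np.full(3, n // 2, dtype=float)
    Minv = _PERM @ np.asarray(R, dtype=float).T @ _PERM  # inverse rotation, zyx basis
    # snap numerically-zero entries so exact symmetries (identity, full turns)
    # do not push edge voxels infinitesimally out of bounds
    Minv[np.abs(Minv) < 1e-12] = 0.0
    Minv[np.abs(Minv - 1.0) < 1e-12] = 1.0
    Minv[np.abs(Minv + 1.0) < 1e-12] = -1.0
    s_idx = np.asarray(shift_xyz, dtype=float)[::-1]
    offset = c - Minv @ (c + s_idx)
    fill = float(data.mean()) if cval is None else float(cval)
    return ndimage.affine_transform(
        data, Minv, offset=offset, order=1, mode="constant", cval=fill,
        prefilter=False, output=np.float32 if data.dtype == np.float32 else None,
    )


def rotate_shift_volume(
    v: DensityVolume,
    e: EulerTriplet | np.ndarray,
    shift_vox=(0.0, 0.0, 0.0),
) -> DensityVolume:
    """Rigid resampling of a cubic volume: rotate by ``e`` about the box
    center, then translate by ``shift_vox`` (x, y, z voxels)."""
    R = e if isinstance(e, np.ndarray) else euler_to_matrix(e)
    n = v.data.shape[0]
    if v.data.shape != (n, n, n):
        raise ValidationError("rotate_shift_volume requires a cubic volume")
    if np.max(np.abs(np.asarray(shift_vox))) > n / 4 + 1e-9:
        raise ValidationError("shift exceeds a quarter of the box")
    return DensityVolume(rotate_array(v.data, R, shift_vox), v.voxel_size_A, v.origin_A)


def invert_pose(R: np.ndarray, shift_xyz) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of pose (R, t) under rotate-then-shift semantics."""
    Rinv = np.asarray(R).T
    return Rinv, -(Rinv @ np.asarray(shift_xyz, dtype=float))


# --------------------------------------------------------------------------
# Tube models and surface seeding
# --------------------------------------------------------------------------


@dataclasses.dataclass
class TubeModel:
    """A traced membrane tubule: centerline polyline (voxels, (x,y,z) rows),
    radius in Å (to the bilayer mid-plane), and identifiers."""

    centerline: np.ndarray
    radius_A: float
    tomo_id: int = 0
    tube_id: int = 0

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValidationError("centerline must be an (N, 3) point list")
        if len(self.centerline) < 2:
            raise ValidationError("centerline needs at least 2 points")
        if not self.radius_A > 0:
            raise ValidationError("radius_A must be positive")

    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def length_vox(self) -> float:
        return float(self.arc_lengths()[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Centerline point at arc length ``s`` (voxels)."""
        arcs = self.arc_lengths()
        s = float(np.clip(s, 0.0, arcs[-1]))
        i = int(np.searchsorted(arcs, s, side="right") - 1)
        i = min(i, len(arcs) - 2)
        denom = max(arcs[i + 1] - arcs[i], 1e-12)
        f = (s - arcs[i]) / denom
        return (1 - f) * self.centerline[i] + f * self.centerline[i + 1]

    def axis_at(self, s: float) -> np.ndarray:
        """Unit local axis at arc length ``s`` (3-point smoothed tangent)."""
        arcs = self.arc_lengths()
        h = max(arcs[-1] / max(len(arcs) - 1, 1), 1e-6)
        p0 = self.point_at(s - h)
        p1 = self.point_at(s + h)
        t = p1 - p0
        nrm = np.linalg.norm(t)
        if nrm < 1e-12:
            raise GeometryError("degenerate centerline tangent")
        return t / nrm

    def project(self, point_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(closest centerline point, local axis) for an arbitrary point."""
        arcs = self.arc_lengths()
        samples = np.linspace(0.0, arcs[-1], max(4 * len(arcs), 64))
        pts = np.array([self.point_at(s) for s in samples])
        d = np.linalg.norm(pts - np.asarray(point_xyz, dtype=float), axis=1)
        i = int(np.argmin(d))
        return pts[i], self.axis_at(samples[i])


def _transported_frames(tube: TubeModel, arc_positions: np.ndarray):
    """Parallel-transported (u, w) normal-plane bases along the centerline."""
    frames = []
    prev_u = None
    for s in arc_positions:
        a = tube.axis_at(s)
        if prev_u is None:
            ref = np.array([1.0, 0.0, 0.0])
            if abs(a @ ref) > 0.9:
                ref = np.array([0.0, 0.0, 1.0])
            u = ref - (ref @ a) * a
        else:
            u = prev_u - (prev_u @ a) * a
        u = u / np.linalg.norm(u)
        w = np.cross(a, u)
        frames.append((a, u, w))
        prev_u = u
    return frames


def initial_orientation(seed_position_xyz, tube: TubeModel) -> EulerTriplet:
    """Membrane-normal initial orientation for a surface seed.

    The particle z-axis maps onto the outward surface normal; the particle
    x-axis onto the circumferential tangent (perpendicular to the tube axis).
    """
    p = np.asarray(seed_position_xyz, dtype=float)
    center, axis = tube.project(p)
    radial = p - center
    radial = radial - (radial @ axis) * axis
    nrm = np.linalg.norm(radial)
    if nrm < 1e-9:
        raise GeometryError("seed lies on the tube centerline; normal undefined")
    n = radial / nrm
    t = np.cross(axis, n)
    R = np.stack([t, np.cross(n, t), n], axis=1)
    return matrix_to_euler(R)


def frame_on_surface(axis: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Rotation matrix with z = outward normal, x = circumferential tangent."""
    n = normal / np.linalg.norm(normal)
    t = np.cross(axis, n)
    t = t / np.linalg.norm(t)
    return np.stack([t, np.cross(n, t), n], axis=1)


def seed_tube_surface(
    tube: TubeModel, spacing_A: float, voxel_size_A: float
) -> pd.DataFrame:
    """Uniformly seed the tube surface: rings every ``spacing_A`` along the
    axis, each carrying round(2*pi*radius/spacing) seeds, with membrane-normal
    initial orientations.  Deterministic (no RNG)."""
    if not spacing_A > 0:
        raise ValidationError("spacing_A must be positive")
    spacing_vox = spacing_A / voxel_size_A
    length = tube.length_vox()
    n_rings = int(np.floor(length / spacing_vox - 1e-9)) + 1 if length >= spacing_vox else 0
    if length < spacing_vox:
        logger.warning(
            "tube %d shorter than spacing (%.1f Å); falling back to a single ring",
            tube.tube_id, spacing_A,
        )
        arc_positions = np.array([length / 2.0])
    else:
        arc_positions = np.arange(n_rings) * spacing_vox
        arc_positions = arc_positions[arc_positions < length - 1e-9]
        if len(arc_positions) == 0:
            arc_positions = np.array([length / 2.0])
    frames = _transported_frames(tube, arc_positions)
    r_vox = tube.radius_A / voxel_size_A
    n_per_ring = max(1, int(round(2 * np.pi * tube.radius_A / spacing_A)))
    rows = []
    for s, (a, u, w) in zip(arc_positions, frames):
        center = tube.point_at(s)
        for j in range(n_per_ring):
            az = 2 * np.pi * j / n_per_ring
            n = np.cos(az) * u + np.sin(az) * w
            pos = center + r_vox * n
            R = frame_on_surface(a, n)
            e = matrix_to_euler(R)
            rows.append((pos, e))
    table = new_particle_table(len(rows))
    table["tomo_id"] = tube.tomo_id
    table["tube_id"] = tube.tube_id
    for i, (pos, e) in enumerate(rows):
        table.loc[i, ["pos_x", "pos_y", "pos_z"]] = pos
        table.loc[i, ["phi", "theta", "psi"]] = e.as_tuple()
    return table
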