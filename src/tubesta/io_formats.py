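"""On-disk artifacts: MRC volumes, tilt files, particle tables, run configs.

Conventions used throughout the package
---------------------------------------
* Volume arrays are indexed ``[z, y, x]`` (slowest to fastest axis), which is
  the natural numpy layout of an MRC file with the default axis mapping
  (mapc, mapr, maps) = (1, 2, 3).
* All 3-vectors exposed in tables and function signatures — positions, shifts,
  centerline points — are ordered ``(x, y, z)`` in units of voxels unless a
  name carries an ``_A`` (ångström) suffix.
* Volumes are written as MRC2014 mode 2 (32-bit float).
* Particle tables are tab-separated text with a header row; one row per
  subtomogram (a "motive list" in the TOM/AV3 tradition, but self-describing).
"""

from __future__ import annotations

import dataclasses
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, SchemaError, ValidationError

# --------------------------------------------------------------------------
# DensityVolume
# --------------------------------------------------------------------------


@dataclasses.dataclass
class DensityVolume:
    """A 3D real-valued density grid with an isotropic voxel size in Å.

    ``data`` is indexed [z, y, x]; ``origin_A`` is the physical (x, y, z)
    position of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size_A: float
    origin_A: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValidationError("DensityVolume data must be 3-dimensional")
        if min(self.data.shape) < 2:
            raise ValidationError("all volume dimensions must be >= 2")
        if not self.voxel_size_A > 0:
            raise ValidationError("voxel_size_A must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.data.copy(), self.voxel_size_A, self.origin_A)


# --------------------------------------------------------------------------
# MRC2014 reading/writing (mode 2 output; modes 0/1/2/6 readable)
# --------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def write_volume(volume: DensityVolume, path: str | Path) -> None:
    """Write ``volume`` as an MRC2014 mode-2 (float32) file."""
    data = np.ascontiguousarray(volume.data, dtype=np.float32)
    nz, ny, nx = data.shape
    vx = float(volume.voxel_size_A)
    header = bytearray(1024)
    ints = [nx, ny, nz, 2, 0, 0, 0, nx, ny, nz]
    struct.pack_into("<10i", header, 0, *ints)
    struct.pack_into("<6f", header, 40, nx * vx, ny * vx, nz * vx, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<2i", header, 88, 1, 0)  # ispg (volume), nsymbt
    struct.pack_into("<3f", header, 196, *[float(o) for o in volume.origin_A])
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0, 0])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 1)  # nlabl
    header[224 : 224 + 80] = b"tubesta volume".ljust(80)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_volume(path: str | Path) -> DensityVolume:
    """Read an MRC2014 volume; data is returned in canonical [z, y, x] order.

    Raises :class:`FormatError` naming the offending header field for corrupt
    or truncated files.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise FormatError(f"{path}: file shorter than the 1024-byte MRC header")
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise FormatError(f"{path}: missing 'MAP ' magic (not an MRC2014 file)")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if min(nx, ny, nz) < 1 or max(nx, ny, nz) > 100_000:
        raise FormatError(f"{path}: implausible dimensions nx/ny/nz = {(nx, ny, nz)}")
    if mode not in _MRC_MODES:
        raise FormatError(f"{path}: unsupported mode {mode}")
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cella = struct.unpack_from("<3f", raw, 40)
    mapc, mapr, maps = struct.unpack_from("<3i", raw, 64)
    if sorted((mapc, mapr, maps)) != [1, 2, 3]:
        raise FormatError(f"{path}: invalid axis map (mapc,mapr,maps)={(mapc, mapr, maps)}")
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if nsymbt < 0:
        raise FormatError(f"{path}: negative nsymbt")
    origin = struct.unpack_from("<3f", raw, 196)
    if mx <= 0 or my <= 0 or mz <= 0:
        raise FormatError(f"{path}: non-positive sampling mx/my/mz")
    spacings = (cella[0] / mx, cella[1] / my, cella[2] / mz)
    if max(spacings) <= 0:
        raise FormatError(f"{path}: cella implies non-positive voxel size")
    if (max(spacings) - min(spacings)) > 1e-3 * max(spacings):
        raise FormatError(f"{path}: anisotropic voxel size in cella {spacings}")
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    count = nx * ny * nz
    start = 1024 + nsymbt
    if len(raw) < start + count * dtype.itemsize:
        raise FormatError(f"{path}: truncated data block (nx*ny*nz exceeds file size)")
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=start)
    # column axis (mapc) varies fastest on disk; reorder to canonical z,y,x
    fast_to_slow = (mapc, mapr, maps)  # axis ids (1=x,2=y,3=z) fastest->slowest
    shape_disk = (nz, ny, nx)
    data = data.reshape(shape_disk)
    if fast_to_slow != (1, 2, 3):
        # permute so that axis id 3 (z) is slowest, 1 (x) fastest
        order = [fast_to_slow[::-1].index(ax) for ax in (3, 2, 1)]
        data = np.transpose(data, order)
    return DensityVolume(
        data.astype(np.float32), float(np.mean(spacings)), tuple(float(o) for o in origin)
    )


# --------------------------------------------------------------------------
# Particle tables
# --------------------------------------------------------------------------

PARTICLE_COLUMNS = [
    "particle_id",
    "tomo_id",
    "tube_id",
    "pos_x",
    "pos_y",
    "pos_z",
    "shift_x",
    "shift_y",
    "shift_z",
    "phi",
    "theta",
    "psi",
    "cc_score",
    "class_id",
    "halfset",
]

_INT_COLS = ["particle_id", "tomo_id", "tube_id"]
_FLOAT_COLS = [
    "pos_x", "pos_y", "pos_z", "shift_x", "shift_y", "shift_z",
    "phi", "theta", "psi", "cc_score",
]
HALFSET_VALUES = ("odd", "even", "unset")


def new_particle_table(n: int = 0) -> pd.DataFrame:
    """An empty particle table with the canonical schema."""
    df = pd.DataFrame({c: np.zeros(n) for c in PARTICLE_COLUMNS})
    for c in _INT_COLS:
        df[c] = np.arange(n) if c == "particle_id" else np.zeros(n, dtype=np.int64)
    for c in _FLOAT_COLS:
        df[c] = np.zeros(n, dtype=np.float64)
    df["cc_score"] = np.nan
    df["class_id"] = pd.array([pd.NA] * n, dtype="Int64")
    df["halfset"] = pd.array(["unset"] * n, dtype="str")
    return df


def validate_particle_table(table: pd.DataFrame) -> None:
    """Enforce the particle-table schema and invariants."""
    missing = [c for c in PARTICLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"particle table missing mandatory columns: {missing}")
    if table["particle_id"].duplicated().any():
        dupes = table.loc[table["particle_id"].duplicated(), "particle_id"].tolist()
        raise SchemaError(f"duplicate particle_id values: {sorted(set(dupes))[:10]}")
    bad = ~table["halfset"].isin(HALFSET_VALUES)
    if bad.any():
        raise SchemaError(f"invalid halfset values: {table.loc[bad, 'halfset'].unique()}")
    cc = table["cc_score"].dropna()
    if len(cc) and ((cc < -1 - 1e-9) | (cc > 1 + 1e-9)).any():
        raise SchemaError("cc_score values outside [-1, 1]")


def write_particle_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_particle_table(table)
    out = table[PARTICLE_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_particle_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"halfset": "str"},
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"{path}: cannot parse particle table: {exc}") from exc
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns: {missing}")
    for c in _INT_COLS:
        df[c] = df[c].astype(np.int64)
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(np.float64)
    df["class_id"] = df["class_id"].astype("Int64")
    df["halfset"] = df["halfset"].fillna("unset").astype("str")
    validate_particle_table(df)
    return df


# --------------------------------------------------------------------------
# Tilt files and tilt schemes
# --------------------------------------------------------------------------


def read_tilt_file(path: str | Path) -> list[float]:
    """Read an IMOD-style .tlt file: one stage tilt in degrees per line."""
    angles: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                angles.append(float(text))
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: not a number: {text!r}"
                ) from exc
    return angles


def write_tilt_file(angles_deg, path: str | Path) -> None:
    Path(path).write_text("".join(f"{a:.2f}\n" for a in angles_deg))


@dataclasses.dataclass
class TiltScheme:
    """A single-axis tilt series: stage angles, temporal order, per-tilt dose.

    ``acquisition_order[t]`` is the index into ``angles_deg`` of the t-th
    acquired tilt. ``dose_per_tilt_eA2`` is aligned with ``angles_deg``.
    """

    angles_deg: np.ndarray
    acquisition_order: np.ndarray
    dose_per_tilt_eA2: np.ndarray

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.acquisition_order = np.asarray(self.acquisition_order, dtype=int)
        self.dose_per_tilt_eA2 = np.asarray(self.dose_per_tilt_eA2, dtype=float)
        n = len(self.angles_deg)
        if len(self.acquisition_order) != n or len(self.dose_per_tilt_eA2) != n:
            raise ValidationError("tilt scheme arrays must have equal length")
        if sorted(self.acquisition_order) != list(range(n)):
            raise ValidationError("acquisition_order must be a permutation")
        if (self.dose_per_tilt_eA2 < 0).any():
            raise ValidationError("doses must be non-negative")

    @property
    def n_tilts(self) -> int:
        return len(self.angles_deg)

    @property
    def total_dose_eA2(self) -> float:
        return float(self.dose_per_tilt_eA2.sum())

    @property
    def tilt_range_deg(self) -> tuple[float, float]:
        return float(self.angles_deg.min()), float(self.angles_deg.max())

    def cumulative_dose_eA2(self) -> np.ndarray:
        """Dose accumulated through each tilt's acquisition (aligned with angles)."""
        cum = np.zeros(self.n_tilts)
        running = 0.0
        for idx in self.acquisition_order:
            running += self.dose_per_tilt_eA2[idx]
            cum[idx] = running
        return cum


def dose_symmetric_scheme(
    tilt_max_deg: float = 60.0,
    n_tilts: int = 41,
    total_dose_eA2: float = 130.0,
) -> TiltScheme:
    """Dose-symmetric single-axis scheme: 0, +s, -s, +2s, -2s, ... (group size 1).

    Defaults reproduce a ±60°, 41-tilt series with ~130 e−/Å² distributed
    equally between tilts.
    """
    if n_tilts < 1 or n_tilts % 2 == 0:
        raise ValidationError("n_tilts must be odd for a symmetric scheme")
    step = 2 * tilt_max_deg / (n_tilts - 1) if n_tilts > 1 else 0.0
    angles = np.linspace(-tilt_max_deg, tilt_max_deg, n_tilts)
    zero = n_tilts // 2
    order = [zero]
    for k in range(1, zero + 1):
        order.append(zero + k)
        order.append(zero - k)
    dose = np.full(n_tilts, total_dose_eA2 / n_tilts)
    scheme = TiltScheme(angles, np.array(order), dose)
    assert abs(scheme.total_dose_eA2 - total_dose_eA2) < 1e-6
    assert step >= 0
    return scheme


# --------------------------------------------------------------------------
# Run configuration (YAML)
# --------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
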