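"""Half-set bookkeeping, Fourier shell correlation, and resolution readout."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import DensityVolume

logger = logging.getLogger(__name__)


def assign_halfsets(table: pd.DataFrame) -> pd.DataFrame:
    """Split particles into odd/even half-sets by tubule parity.

    All particles of one tube share a half-set, so the halves are spatially
    independent (no shared coat lattice), the condition for a meaningful FSC.
    """
    if "tube_id" not in table.columns or table["tube_id"].isna().any():
        raise ValidationError("assign_halfsets requires tube_id on all records")
    out = table.copy()
    parity = out["tube_id"].to_numpy(dtype=int) % 2
    out["halfset"] = np.where(parity == 1, "odd", "even")
    if len(set(out["halfset"])) < 2 and len(out):
        logger.warning(
            "all particles fall in the %s half-set (single tube?); FSC impossible",
            out["halfset"].iloc[0],
        )
    return out


@dataclasses.dataclass
class FSCCurve:
    """Per-shell correlation between two half-maps.

    ``shell_freq_A_inv`` holds shell-center spatial frequencies (1/Å);
    ``n_voxels_per_shell`` counts independent Fourier coefficients per shell
    (conjugate-symmetric halves counted once).
    """

    shell_freq_A_inv: np.ndarray
    fsc: np.ndarray
    n_voxels_per_shell: np.ndarray
    voxel_size_A: float


def fsc(
    map_a: DensityVolume,
    map_b: DensityVolume,
    real_mask: np.ndarray | None = None,
    shell_width_voxels: float = 1.0,
) -> FSCCurve:
    """Fourier shell correlation after soft real-space masking."""
    a = map_a.data.astype(np.float64)
    b = map_b.data.astype(np.float64)
    if a.shape != b.shape:
        raise ValidationError("FSC requires identically shaped maps")
    if abs(map_a.voxel_size_A - map_b.voxel_size_A) > 1e-6:
        raise ValidationError("FSC requires equal voxel sizes")
    if real_mask is not None:
        a = a * real_mask
        b = b * real_mask
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    n = a.shape[0]
    grids = np.meshgrid(*[np.fft.fftfreq(m) * m for m in a.shape], indexing="ij")
    r = np.sqrt(sum(g**2 for g in grids))
    shell = np.round(r / shell_width_voxels).astype(int)
    n_shells = n // 2 + 1
    inside = shell < n_shells
    s = shell[inside]
    cross = np.bincount(s, weights=(fa * np.conj(fb)).real[inside], minlength=n_shells)
    pa = np.bincount(s, weights=np.abs(fa[inside]) ** 2, minlength=n_shells)
    pb = np.bincount(s, weights=np.abs(fb[inside]) ** 2, minlength=n_shells)
    counts = np.bincount(s, minlength=n_shells)
    denom = np.sqrt(pa * pb)
    curve = np.where(denom > 0, cross / np.maximum(denom, 1e-300), 0.0)
    freqs = np.arange(n_shells) * shell_width_voxels / (n * map_a.voxel_size_A)
    # Hermitian mates carry identical information: count each pair once
    n_indep = np.maximum(counts // 2, 1)
    return FSCCurve(freqs, np.clip(curve, -1.0, 1.0), n_indep, map_a.voxel_size_A)


@dataclasses.dataclass
class ResolutionEstimate:
    resolution_A: float
    threshold: float
    crossed: bool  # False: curve never fell below threshold (Nyquist-limited)


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> ResolutionEstimate:
    """First crossing of the FSC below ``threshold``, linearly interpolated
    between shells; 0.143 is the gold-standard criterion for independently
    refined half-sets."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    f = np.asarray(curve.fsc)
    freqs = np.asarray(curve.shell_freq_A_inv)
    if len(f) == 0:
        raise ValidationError("empty FSC curve")
    nyquist_A = 2.0 * curve.voxel_size_A
    for i in range(1, len(f)):
        if f[i] < threshold <= f[i - 1]:
            df = f[i - 1] - f[i]
            frac = (f[i - 1] - threshold) / df if df > 0 else 0.0
            freq = freqs[i - 1] + frac * (freqs[i] - freqs[i - 1])
            return ResolutionEstimate(float(1.0 / freq), threshold, True)
    logger.info("FSC never crossed %.3f; resolution is Nyquist-limited", threshold)
    return ResolutionEstimate(float(nyquist_A), threshold, False)


def write_fsc_curve(curve: FSCCurve, path) -> None:
    rows = np.column_stack([curve.shell_freq_A_inv, curve.fsc, curve.n_voxels_per_shell])
    header = "freq_A_inv\tfsc\tn_indep_voxels"
    np.savetxt(path, rows, delimiter="\t", header=header, comments="")
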