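"""Fourier-domain weights: missing-wedge masks, CTF amplitude profiles,
cumulative-exposure filters, band-passes, and the per-particle composite mask.

All masks are stored DC-centered (zero frequency at voxel N//2 on each axis)
on [z,y,x] grids and take values in [0, 1].  The tilt axis is fixed along +y
in the volume frame: at stage tilt alpha the beam direction is
(sin(alpha), 0, cos(alpha)), so a single-axis series samples a double-wedge
("bow-tie") of Fourier space that leaves a missing wedge around kz.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .errors import ValidationError
from .io_formats import TiltScheme

logger = logging.getLogger(__name__)

# published critical-exposure curve Ne(k) = a*k^b + c (k in 1/Å, Ne in e-/Å^2)
CRITICAL_EXPOSURE_A = 0.245
CRITICAL_EXPOSURE_B = -1.665
CRITICAL_EXPOSURE_C = 2.81


@dataclasses.dataclass
class FourierMask:
    """A non-negative Fourier-domain weight grid (DC-centered, [z,y,x])."""

    weights: np.ndarray
    tilt_range_deg: tuple[float, float] | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float32)
        if self.weights.ndim != 3:
            raise ValidationError("mask weights must be 3-dimensional")
        if float(self.weights.min()) < -1e-6 or float(self.weights.max()) > 1 + 1e-6:
            raise ValidationError("mask weights must lie in [0, 1]")

    @property
    def shape(self):
        return self.weights.shape

    def unshifted(self) -> np.ndarray:
        """Weights in numpy FFT layout (DC at index 0)."""
        return np.fft.ifftshift(self.weights)

    def rfft_weights(self) -> np.ndarray:
        """Weights in rfftn layout (half grid along the last axis)."""
        full = self.unshifted()
        return np.ascontiguousarray(full[..., : full.shape[-1] // 2 + 1])


def centered_index_grids(shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer Fourier-voxel coordinates (kz, ky, kx) with DC at N//2."""
    axes = [np.arange(n) - n // 2 for n in shape]
    return np.meshgrid(*axes, indexing="ij")  # type: ignore[return-value]


def centered_freq_magnitude(shape, voxel_size_A: float) -> np.ndarray:
    """|k| in 1/Å on the DC-centered grid."""
    kz, ky, kx = centered_index_grids(shape)
    fz = kz / (shape[0] * voxel_size_A)
    fy = ky / (shape[1] * voxel_size_A)
    fx = kx / (shape[2] * voxel_size_A)
    return np.sqrt(fx**2 + fy**2 + fz**2)


# --------------------------------------------------------------------------
# Binary missing-wedge mask
# --------------------------------------------------------------------------


def binary_wedge(
    shape, tilt_min_deg: float, tilt_max_deg: float, tilt_axis: str = "y"
) -> FourierMask:
    """Binary mask of the Fourier region sampled by a single-axis tilt series.

    A voxel is 1 iff some stage tilt alpha in [tilt_min, tilt_max] has its
    central section passing through it, i.e. alpha = -atan2(kz, kx) mod 180.
    The DC voxel and the tilt-axis line (kx = kz = 0) are always sampled.
    """
    if tilt_axis != "y":
        raise ValidationError("tilt axis is fixed along +y in this package")
    if not (-90.0 <= tilt_min_deg < tilt_max_deg <= 90.0):
        raise ValidationError("require -90 <= tilt_min < tilt_max <= 90")
    kz, ky, kx = centered_index_grids(shape)
    theta = np.degrees(np.arctan2(kz, kx))
    alpha = -theta
    alpha = np.mod(alpha + 90.0, 180.0) - 90.0  # wrap into (-90, 90]
    eps = 1e-9
    inside = (alpha >= tilt_min_deg - eps) & (alpha <= tilt_max_deg + eps)
    # the wrap point: alpha = -90 and +90 describe the same section
    inside |= (np.abs(alpha - 90.0) < eps) & (tilt_min_deg - eps <= -90.0 + eps)
    inside |= (np.abs(alpha + 90.0) < eps) & (tilt_max_deg + eps >= 90.0 - eps)
    inside |= (kx == 0) & (kz == 0)  # tilt axis and DC
    return FourierMask(
        inside.astype(np.float32),
        tilt_range_deg=(tilt_min_deg, tilt_max_deg),
        metadata={"kind": "binary_wedge"},
    )


# --------------------------------------------------------------------------
# CTF amplitude profile
# --------------------------------------------------------------------------


def electron_wavelength_A(voltage_kV: float) -> float:
    v = voltage_kV * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


@dataclasses.dataclass(frozen=True)
class CTFProfile:
    """|CTF|(k): amplitude modulation of a phase-flipped contrast transfer
    function for the given optics.  Callable on spatial frequency in 1/Å."""

    defocus_um: float
    voltage_kV: float
    cs_mm: float
    amplitude_contrast: float

    def phase(self, k) -> np.ndarray:
        """Aberration phase chi(k); underfocus makes it negative-going."""
        lam = electron_wavelength_A(self.voltage_kV)
        dz = self.defocus_um * 1e4  # Å
        cs = self.cs_mm * 1e7  # Å
        k = np.asarray(k, dtype=float)
        return -np.pi * lam * dz * k**2 + 0.5 * np.pi * cs * lam**3 * k**4

    def __call__(self, k) -> np.ndarray:
        a = self.amplitude_contrast
        chi = self.phase(k)
        ctf = np.sqrt(1.0 - a * a) * np.sin(chi) - a * np.cos(chi)
        return np.abs(ctf)


def ctf_amplitude_profile(
    defocus_um: float,
    voltage_kV: float = 300.0,
    cs_mm: float = 2.7,
    amplitude_contrast: float = 0.07,
) -> CTFProfile:
    if not defocus_um > 0:
        raise ValidationError("defocus must be positive (underfocus)")
    if voltage_kV not in (200.0, 300.0, 200, 300):
        raise ValidationError("voltage must be 200 or 300 kV")
    if cs_mm < 0:
        raise ValidationError("spherical aberration must be non-negative")
    if not 0.0 <= amplitude_contrast < 1.0:
        raise ValidationError("amplitude contrast must be in [0, 1)")
    return CTFProfile(float(defocus_um), float(voltage_kV), float(cs_mm),
                      float(amplitude_contrast))


# --------------------------------------------------------------------------
# Cumulative-exposure filter
# --------------------------------------------------------------------------


def critical_exposure_eA2(k, a=CRITICAL_EXPOSURE_A, b=CRITICAL_EXPOSURE_B,
                          c=CRITICAL_EXPOSURE_C) -> np.ndarray:
    """Critical exposure Ne(k) = a*k^b + c (published curve; k in 1/Å)."""
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore"):
        ne = np.where(k > 0, a * np.power(np.maximum(k, 1e-12), b) + c, np.inf)
    return ne


def exposure_filter(cumulative_dose_eA2: float, frequency_grid,
                    **curve_params) -> np.ndarray:
    """Dose-dependent amplitude attenuation exp(-N / (2*Ne(k)))."""
    if cumulative_dose_eA2 < 0:
        raise ValidationError("cumulative dose must be non-negative")
    ne = critical_exposure_eA2(frequency_grid, **curve_params)
    with np.errstate(over="ignore"):
        att = np.exp(-cumulative_dose_eA2 / (2.0 * ne))
    return att


# --------------------------------------------------------------------------
# Band-pass
# --------------------------------------------------------------------------


def _raised_cosine_lowpass(f: np.ndarray, f_cut: float, soft: float) -> np.ndarray:
    """1 below f_cut*(1-soft), cosine edge to 0 at f_cut*(1+soft)."""
    if soft <= 0:
        return (f <= f_cut + 1e-12).astype(np.float64)
    f1, f2 = f_cut * (1 - soft), f_cut * (1 + soft)
    w = np.clip((f - f1) / max(f2 - f1, 1e-12), 0.0, 1.0)
    return 0.5 * (1 + np.cos(np.pi * w))


def bandpass(
    shape,
    voxel_size_A: float,
    highcut_A: float,
    lowcut_A: float | None = None,
    soft_edge_frac: float = 0.3,
) -> FourierMask:
    """Raised-cosine band-pass between 1/lowcut_A and 1/highcut_A.

    ``lowcut_A`` (low-resolution cut, larger Å) of None disables the
    high-pass side; a ``highcut_A`` at or beyond Nyquist disables the
    low-pass side (clipped, with a warning when strictly beyond).
    """
    if lowcut_A is not None and not lowcut_A > highcut_A:
        raise ValidationError("lowcut_A must be a lower resolution (larger Å) than highcut_A")
    f = centered_freq_magnitude(shape, voxel_size_A)
    nyq = 1.0 / (2.0 * voxel_size_A)
    w = np.ones_like(f)
    f_high = 1.0 / highcut_A
    if f_high < nyq - 1e-12:
        w *= _raised_cosine_lowpass(f, f_high, soft_edge_frac)
    elif f_high > nyq + 1e-12:
        logger.warning("highcut %.2f Å is beyond Nyquist (%.2f Å); clipped", highcut_A,
                       2 * voxel_size_A)
    if lowcut_A is not None and np.isfinite(lowcut_A):
        f_low = 1.0 / lowcut_A
        if f_low > 1e-12:
            w *= 1.0 - _raised_cosine_lowpass(f, f_low, soft_edge_frac)
    # DC must pass for mean-preserving filters unless a high-pass was requested
    if lowcut_A is None or not np.isfinite(lowcut_A):
        c = tuple(n // 2 for n in shape)
        w[c] = 1.0
    return FourierMask(w.astype(np.float32), metadata={
        "kind": "bandpass", "lowcut_A": lowcut_A, "highcut_A": highcut_A,
        "soft_edge_frac": soft_edge_frac,
    })


def allpass(shape) -> FourierMask:
    return FourierMask(np.ones(shape, dtype=np.float32), metadata={"kind": "allpass"})


# --------------------------------------------------------------------------
# Composite per-particle mask: wedge x CTF x exposure (x band-pass)
# --------------------------------------------------------------------------


def composite_particle_mask(
    wedge: FourierMask,
    ctf_profile: CTFProfile | None,
    tilt_scheme: TiltScheme,
    voxel_size_A: float,
    bandpass_mask: FourierMask | None = None,
    apod_vox: float = 2.0,
) -> FourierMask:
    """Modified wedge mask: per-tilt central sections carrying |CTF| times the
    cumulative-exposure attenuation of that tilt; overlaps take the maximum.

    Sections are one voxel thick with a raised-cosine falloff over
    ``apod_vox`` voxels; the result is clipped by the binary wedge so the
    composite never exceeds it.
    """
    shape = wedge.shape
    if wedge.tilt_range_deg is not None:
        lo, hi = wedge.tilt_range_deg
        for a in tilt_scheme.angles_deg:
            if a < lo - 1e-9 or a > hi + 1e-9:
                raise ValidationError(f"tilt {a}° lies outside the wedge range {lo}..{hi}°")
    kz, ky, kx = centered_index_grids(shape)
    fmag = centered_freq_magnitude(shape, voxel_size_A)
    ctf2d = ctf_profile(fmag) if ctf_profile is not None else np.ones_like(fmag)
    cum = tilt_scheme.cumulative_dose_eA2()
    composite = np.zeros(shape, dtype=np.float64)
    for i, alpha in enumerate(tilt_scheme.angles_deg):
        b = np.deg2rad(alpha)
        d = np.abs(kx * np.sin(b) + kz * np.cos(b))  # voxels from the section plane
        if apod_vox > 0:
            sec = np.clip((d - 0.5) / apod_vox, 0.0, 1.0)
            sec = 0.5 * (1 + np.cos(np.pi * sec))
        else:
            sec = (d <= 0.5).astype(np.float64)
        w = sec * ctf2d * exposure_filter(float(cum[i]), fmag)
        np.maximum(composite, w, out=composite)
    n_angles = len(np.unique(tilt_scheme.angles_deg))
    if n_angles > 1:
        composite *= wedge.weights
    if bandpass_mask is not None:
        composite *= bandpass_mask.weights
    return FourierMask(
        composite.astype(np.float32),
        tilt_range_deg=wedge.tilt_range_deg,
        metadata={
            "kind": "composite",
            "defocus_um": getattr(ctf_profile, "defocus_um", None),
            "total_dose_eA2": tilt_scheme.total_dose_eA2,
            "bandpass": None if bandpass_mask is None else bandpass_mask.metadata,
        },
    )
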