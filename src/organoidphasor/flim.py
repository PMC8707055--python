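"""Phasor transform of fluorescence decay histograms.

Fit-free lifetime analysis: each pixel's photon-arrival histogram is mapped
to first-harmonic Fourier coordinates

    g = sum_k I_k cos(n w t_k) / sum_k I_k
    s = sum_k I_k sin(n w t_k) / sum_k I_k

with t_k the bin centers and w = 2*pi / rep_period. Mono-exponential decays
fall on the universal circle (g - 1/2)^2 + s^2 = 1/4; mixtures fall inside
it on the chord between their components, split by intensity weight. A
reference compound of known lifetime (coumarin 6, 2.5 ns) supplies the
rotation + scaling that removes the instrument's phase and modulation
distortion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .synth import DecayCube

__all__ = [
    "PhasorField",
    "CalibrationFactors",
    "decay_to_phasor",
    "derive_calibration",
    "apply_calibration",
    "universal_circle_point",
    "lifetime_from_phasor",
    "median_filter_phasor",
]

#: Tolerance for universal-circle membership of calibrated noiseless
#: mono-exponential pixels (n_bins >= 256).
CIRCLE_TOL = 1e-3


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates plus total intensity.

    ``g`` and ``s`` hold NaN at missing pixels (zero recorded intensity),
    which are excluded from every downstream statistic — they must never
    masquerade as long-lifetime pixels at the origin.
    """

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    omega: float
    harmonic: int = 1
    calibrated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.g.shape == self.s.shape == self.intensity.shape):
            raise ValueError("g, s and intensity must share one shape")
        if self.harmonic < 1:
            raise ValueError("harmonic must be >= 1")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    @property
    def defined(self) -> np.ndarray:
        """Mask of pixels with a defined phasor."""
        return ~np.isnan(self.g)


@dataclass
class CalibrationFactors:
    """Rotation + scaling that moves raw phasors onto their true positions."""

    phase_correction: float
    modulation_correction: float
    tau_ref: float
    omega: float

    def __post_init__(self) -> None:
        if self.modulation_correction <= 0:
            raise ValueError("modulation_correction must be positive")


def decay_to_phasor(cube: DecayCube, harmonic: int = 1) -> PhasorField:
    """Transform a decay cube to an (uncalibrated) phasor field.

    Zero-intensity pixels get NaN phasor coordinates; an all-zero cube
    yields an all-missing field with a warning rather than a failure.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    omega = 2.0 * np.pi / cube.rep_period
    t = cube.bin_centers
    cosw = np.cos(harmonic * omega * t)
    sinw = np.sin(harmonic * omega * t)

    intensity = cube.counts.sum(axis=2)
    if not np.any(intensity > 0):
        warnings.warn("decay cube has no photons; phasor field is all-missing", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (cube.counts * cosw).sum(axis=2) / intensity
        s = (cube.counts * sinw).sum(axis=2) / intensity
    empty = intensity == 0
    g[empty] = np.nan
    s[empty] = np.nan

    return PhasorField(
        g=g,
        s=s,
        intensity=intensity,
        omega=omega,
        harmonic=harmonic,
        calibrated=False,
        meta=dict(cube.meta),
    )


def universal_circle_point(tau: float, omega: float) -> tuple[float, float]:
    """Phasor coordinates of a mono-exponential lifetime.

    (g, s) = (1, wt) / (1 + (wt)^2); tau = 0 maps to (1, 0) and tau -> inf
    approaches the origin along the universal circle.
    """
    if tau < 0:
        raise ValueError("lifetime must be nonnegative")
    wt = omega * tau
    denom = 1.0 + wt * wt
    return 1.0 / denom, wt / denom


def derive_calibration(reference: PhasorField, tau_ref: float = 2.5) -> CalibrationFactors:
    """Compute calibration factors from a reference-compound field.

    The intensity-weighted mean phasor of the reference (robust to
    per-pixel noise) is rotated and scaled onto the universal-circle point
    of the known reference lifetime; the same correction then applies to
    every sample pixel.
    """
    if reference.calibrated:
        raise ValueError("reference field is already calibrated")
    if tau_ref <= 0:
        raise ValueError("tau_ref must be positive")
    ok = reference.defined
    if not np.any(ok):
        raise ValueError("reference field has no defined pixels")
    w = reference.intensity[ok]
    mg = float(np.average(reference.g[ok], weights=w))
    ms = float(np.average(reference.s[ok], weights=w))
    modulus = np.hypot(mg, ms)
    if modulus < 1e-12:
        raise ValueError("mean reference phasor at origin; cannot calibrate")

    g_t, s_t = universal_circle_point(tau_ref, reference.omega)
    phase = float(np.arctan2(s_t, g_t) - np.arctan2(ms, mg))
    scale = float(np.hypot(g_t, s_t) / modulus)
    return CalibrationFactors(
        phase_correction=phase,
        modulation_correction=scale,
        tau_ref=tau_ref,
        omega=reference.omega,
    )


def apply_calibration(fieldv: PhasorField, cal: CalibrationFactors) -> PhasorField:
    """Rotate and scale every phasor about the origin; intensity unchanged."""
    if fieldv.calibrated:
        raise ValueError("field is already calibrated")
    if not np.isclose(fieldv.omega, cal.omega):
        raise ValueError(
            f"omega mismatch: field {fieldv.omega} vs calibration {cal.omega}"
        )
    c, s = np.cos(cal.phase_correction), np.sin(cal.phase_correction)
    m = cal.modulation_correction
    g_new = m * (fieldv.g * c - fieldv.s * s)
    s_new = m * (fieldv.g * s + fieldv.s * c)
    return replace(fieldv, g=g_new, s=s_new, calibrated=True)


def lifetime_from_phasor(
    g: float | np.ndarray, s: float | np.ndarray, omega: float
) -> tuple[np.ndarray, np.ndarray]:
    """Invert phasor coordinates to phase and modulation lifetimes.

    tau_phase = s / (g * w); tau_mod = (1/w) * sqrt(1/(g^2 + s^2) - 1).
    The two agree for noiseless mono-exponentials and bracket each other
    for mixtures. Undefined cases are reported as NaN, never clamped:
    tau_phase where g <= 0, tau_mod where g^2 + s^2 > 1 (outside the unit
    circle, unphysical).
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau_phase = np.where(g > 0, s / (g * omega), np.nan)
        msq = g * g + s * s
        inner = 1.0 / msq - 1.0
        tau_mod = np.where(
            (msq > 0) & (inner >= 0), np.sqrt(np.abs(inner)) / omega, np.nan
        )
    if tau_phase.ndim == 0:
        return float(tau_phase), float(tau_mod)
    return tau_phase, tau_mod


def _nan_median_filter(a: np.ndarray, window: int) -> np.ndarray:
    """Median filter that ignores NaN neighbors (NaN pixels stay NaN)."""
    k = window // 2
    padded = np.pad(a, k, mode="constant", constant_values=np.nan)
    stack = np.stack(
        [
            padded[i : i + a.shape[0], j : j + a.shape[1]]
            for i in range(window)
            for j in range(window)
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        out = np.nanmedian(stack, axis=0)
    out[np.isnan(a)] = np.nan
    return out


def median_filter_phasor(fieldv: PhasorField, window: int = 3) -> PhasorField:
    """Spatially median-filter g and s independently; intensity untouched.

    Standard phasor-plot noise reduction: the median acts on the phasor
    coordinates, not the photon histograms, so lifetimes are smoothed
    without mixing counts across pixels. Missing pixels are excluded from
    each window and remain missing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window == 1:
        return replace(fieldv)
    return replace(
        fieldv,
        g=_nan_median_filter(fieldv.g, window),
        s=_nan_median_filter(fieldv.s, window),
    )
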