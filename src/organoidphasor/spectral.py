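"""Spectral phasor analysis of hyperspectral image cubes.

Each pixel's 32-channel emission spectrum is mapped to one point of the
spectral phasor plane via first-harmonic cosine/sine sums over the channel
index:

    G = sum_c I_c cos(2 pi n c / C) / sum_c I_c
    S = sum_c I_c sin(2 pi n c / C) / sum_c I_c

The transform is scale-invariant and linear in intensity, so each
fluorophore species occupies a fixed "fingerprint" location and mixtures
fall on chords between fingerprints. Segmentation is by cursor: a circular
region drawn on the phasor plane selects the pixels whose phasor falls
inside it, and those pixels are recolored on the image — here used to
visualize the retinol distribution that marks functional photoreceptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import EndmemberSpectrum, SpectralCube

__all__ = [
    "SpectralPhasorField",
    "PhasorCursor",
    "spectrum_to_phasor",
    "endmember_phasor",
    "cursor_select",
    "recolor_selection",
    "total_intensity_image",
]

#: Pixels dimmer than this fraction of the 99th-percentile intensity are
#: treated as undefined, keeping dark background off the phasor plot.
DEFAULT_THRESHOLD_FRACTION = 0.01


@dataclass
class SpectralPhasorField:
    """Per-pixel spectral phasor coordinates (G, S) plus summed intensity."""

    G: np.ndarray
    S: np.ndarray
    intensity: np.ndarray
    n_channels: int
    harmonic: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.G.shape == self.S.shape == self.intensity.shape):
            raise ValueError("G, S and intensity must share one shape")
        if self.harmonic < 1:
            raise ValueError("harmonic must be >= 1")
        mod = self.G**2 + self.S**2
        if np.nanmax(mod, initial=0.0) > 1.0 + 1e-9:
            raise ValueError("spectral phasor modulus exceeds 1")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.G)


@dataclass
class PhasorCursor:
    """Circular selection region on the spectral phasor plane."""

    center: tuple[float, float]
    radius: float
    label: str = "selection"
    color: tuple[int, int, int] = (255, 0, 0)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cursor radius must be positive")
        if np.hypot(*self.center) > 1.0 + 1e-9:
            raise ValueError("cursor center must lie within the unit disk")


def _phasor_basis(n_channels: int, harmonic: int) -> tuple[np.ndarray, np.ndarray]:
    # channel index, not wavelength, defines the Fourier phase: the full
    # detector range maps onto one period of harmonic 1
    phase = 2.0 * np.pi * harmonic * np.arange(n_channels) / n_channels
    return np.cos(phase), np.sin(phase)


def spectrum_to_phasor(
    cube: SpectralCube,
    harmonic: int = 1,
    intensity_threshold: float | None = None,
) -> SpectralPhasorField:
    """Transform a spectral cube to the phasor plane.

    Pixels whose channel-summed intensity falls below the threshold
    (default: 1% of the 99th-percentile pixel intensity) are marked missing.
    """
    if cube.n_channels < 2:
        raise ValueError("need at least 2 spectral channels")
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    cosb, sinb = _phasor_basis(cube.n_channels, harmonic)
    total = cube.intensity.sum(axis=2)
    if intensity_threshold is None:
        ref = np.percentile(total, 99)
        intensity_threshold = DEFAULT_THRESHOLD_FRACTION * ref
    with np.errstate(invalid="ignore", divide="ignore"):
        G = (cube.intensity * cosb).sum(axis=2) / total
        S = (cube.intensity * sinb).sum(axis=2) / total
    dim = ~(total > intensity_threshold) | (total == 0)
    G[dim] = np.nan
    S[dim] = np.nan
    return SpectralPhasorField(
        G=G,
        S=S,
        intensity=total,
        n_channels=cube.n_channels,
        harmonic=harmonic,
        meta=dict(cube.meta),
    )


def endmember_phasor(
    spectrum: EndmemberSpectrum, harmonic: int = 1
) -> tuple[float, float]:
    """Phasor fingerprint of a single emission profile.

    Used to seed cursor placement: a cursor centered on an endmember's
    fingerprint selects the pixels that species dominates.
    """
    emission = np.asarray(spectrum.emission, dtype=float)
    total = emission.sum()
    if total <= 0:
        raise ValueError("cannot place a zero spectrum on the phasor plane")
    cosb, sinb = _phasor_basis(len(emission), harmonic)
    return float((emission * cosb).sum() / total), float((emission * sinb).sum() / total)


def cursor_select(fieldv: SpectralPhasorField, cursor: PhasorCursor) -> np.ndarray:
    """Mask of defined pixels whose (G, S) lies inside the cursor circle."""
    d2 = (fieldv.G - cursor.center[0]) ** 2 + (fieldv.S - cursor.center[1]) ** 2
    with np.errstate(invalid="ignore"):
        return fieldv.defined & (d2 <= cursor.radius**2)


def total_intensity_image(cube: SpectralCube) -> np.ndarray:
    """Channel-summed intensity: the total autofluorescence image."""
    return cube.intensity.sum(axis=2)


def recolor_selection(
    cube: SpectralCube, mask: np.ndarray, cursor: PhasorCursor
) -> np.ndarray:
    """Paint cursor-selected pixels over the grayscale intensity image.

    Returns a uint8 RGB image: total intensity rescaled to [0, 255] as the
    grayscale base, with masked pixels in the cursor's color (intensity
    preserved as brightness so the underlying structure stays visible).
    """
    if mask.shape != cube.frame_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame {cube.frame_shape}"
        )
    total = total_intensity_image(cube)
    peak = total.max()
    base = (total / peak if peak > 0 else total).clip(0, 1)
    rgb = np.repeat((base[..., None] * 255).astype(np.uint8), 3, axis=2)
    tint = np.asarray(cursor.color, dtype=float) / 255.0
    rgb[mask] = (base[mask, None] * tint * 255).astype(np.uint8)
    return rgb
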