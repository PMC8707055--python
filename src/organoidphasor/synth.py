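"""Synthetic organoid phantoms and simulated acquisitions.

This module generates everything the analysis stages consume, with known
ground truth attached: laminated ring-shaped organoid cross-sections whose
outer rim is glycolytic (high free-NADH intensity fraction) and whose
interior is more oxidative; time-resolved photon-count cubes built from
periodic bin-integrated exponential decays with optional Poisson noise;
32-channel emission-spectrum cubes mixed from endmember profiles (a
retinol-like component concentrated in the rim); reference-compound decays
with an injectable instrument distortion for calibration to undo; and toy
qPCR cycle-threshold tables with a housekeeping gene, a day-0 control
group, and non-detected wells.

All generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OrganoidPhantom",
    "DecayCube",
    "SpectralCube",
    "EndmemberSpectrum",
    "QPCRTable",
    "NON_DETECTED",
    "DEFAULT_REP_PERIOD_NS",
    "default_channel_centers",
    "default_endmembers",
    "gaussian_endmember",
    "make_organoid_phantom",
    "simulate_decay_cube",
    "make_reference_decay",
    "simulate_spectral_cube",
    "make_qpcr_table",
]

#: Laser repetition period in ns. 12.5 ns corresponds to the 80 MHz pulse
#: rate of a standard Ti:Sapphire two-photon source; the phasor angular
#: frequency is omega = 2*pi / rep_period.
DEFAULT_REP_PERIOD_NS = 12.5

#: Sentinel used in qPCR tables for wells with no detected amplification.
NON_DETECTED = "ND"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OrganoidPhantom:
    """Ground-truth cross-section of a laminated spherical organoid.

    Attributes
    ----------
    label_image
        Integer label per pixel: 0 = background, 1 = outer rim,
        2 = inner mass (extensible).
    free_fraction_map
        Ground-truth free-NADH intensity fraction per pixel, in [0, 1];
        0 on background.
    spectral_weight_maps
        Per-endmember nonnegative abundance per pixel; per-pixel sum <= 1,
        remainder is dark.
    pixel_size
        Micrometers per pixel.
    meta
        Generation parameters (radii, fractions, seed).
    """

    label_image: np.ndarray
    free_fraction_map: np.ndarray
    spectral_weight_maps: dict[str, np.ndarray]
    pixel_size: float = 1.66
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.label_image.shape
        if self.free_fraction_map.shape != shape:
            raise ValueError("label_image and free_fraction_map shapes differ")
        for name, m in self.spectral_weight_maps.items():
            if m.shape != shape:
                raise ValueError(f"abundance map {name!r} shape differs from labels")
            if np.any(m < 0):
                raise ValueError(f"abundance map {name!r} has negative values")
        if np.any(self.free_fraction_map < 0) or np.any(self.free_fraction_map > 1):
            raise ValueError("free_fraction_map outside [0, 1]")
        if np.any(self.free_fraction_map[self.label_image == 0] != 0):
            raise ValueError("free_fraction_map must be 0 on background")
        total = sum(self.spectral_weight_maps.values()) if self.spectral_weight_maps else 0.0
        # tolerance admits single-precision storage round-trips
        if self.spectral_weight_maps and np.any(np.asarray(total) > 1 + 1e-6):
            raise ValueError("spectral abundances sum above 1 somewhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_image.shape

    @property
    def foreground(self) -> np.ndarray:
        return self.label_image > 0


@dataclass
class DecayCube:
    """Per-pixel photon-arrival histogram over one laser repetition period.

    ``counts`` is indexed (y, x, time_bin); nonnegative integers when
    simulated with Poisson noise, nonnegative reals otherwise.
    """

    counts: np.ndarray
    rep_period: float = DEFAULT_REP_PERIOD_NS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError("counts must be a (y, x, time_bin) array")
        if self.n_bins < 16:
            raise ValueError(f"need at least 16 time bins, got {self.n_bins}")
        if self.rep_period <= 0:
            raise ValueError("rep_period must be positive")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def bin_width(self) -> float:
        return self.rep_period / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin timestamps t_k = (k + 1/2) * bin_width, k = 0..n_bins-1."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]


@dataclass
class SpectralCube:
    """Hyperspectral intensity image, indexed (y, x, channel)."""

    intensity: np.ndarray
    channel_centers: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a (y, x, channel) array")
        self.channel_centers = np.asarray(self.channel_centers, dtype=float)
        if len(self.channel_centers) != self.n_channels:
            raise ValueError("channel_centers length must match channel axis")
        if np.any(np.diff(self.channel_centers) <= 0):
            raise ValueError("channel_centers must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.intensity.shape[:2]


@dataclass
class EndmemberSpectrum:
    """Unit-normalized emission profile of one fluorophore species."""

    name: str
    emission: np.ndarray

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=float)
        if np.any(self.emission < 0):
            raise ValueError(f"endmember {self.name!r} has negative emission")
        total = self.emission.sum()
        if total <= 0:
            raise ValueError(f"endmember {self.name!r} is all zero")
        if abs(total - 1.0) > 1e-9:
            self.emission = self.emission / total


@dataclass
class QPCRTable:
    """Long-format qPCR plate: one row per (group, gene, replicate) well.

    ``data`` columns: group_id, gene_id, replicate_id, ct. Non-detected
    wells carry NaN in ``ct`` (serialized as an empty cell). Exactly one
    housekeeping gene and one control group are designated.
    """

    data: pd.DataFrame
    housekeeping_gene: str
    control_group: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"group_id", "gene_id", "replicate_id", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
        detected = self.data["ct"].dropna()
        if np.any(detected <= 0) or np.any(detected > 40):
            raise ValueError("detected Ct values must lie in (0, 40]")
        groups = self.data["group_id"].unique()
        if self.control_group not in groups:
            raise ValueError(f"control group {self.control_group!r} absent from table")
        hk = self.data[self.data["gene_id"] == self.housekeeping_gene]
        for g in groups:
            if hk[hk["group_id"] == g].empty:
                raise ValueError(
                    f"group {g!r} lacks a replicate of housekeeping gene "
                    f"{self.housekeeping_gene!r}"
                )

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.data["gene_id"]))

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group_id"]))

    @property
    def n_nondetected(self) -> int:
        return int(self.data["ct"].isna().sum())


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------


def make_organoid_phantom(
    height: int = 256,
    width: int = 256,
    outer_radius: float = 100,
    rim_thickness: float = 15,
    rim_free_fraction: float = 0.7,
    core_free_fraction: float = 0.3,
    seed: int = 0,
    pixel_size: float = 1.66,
    rim_retinol: float = 0.7,
    core_retinol: float = 0.05,
) -> OrganoidPhantom:
    """Build a two-layer circular organoid phantom with known ground truth.

    The cross-section is a disk centered in the frame: an outer annulus of
    width ``rim_thickness`` labeled 1 (the photoreceptor rim — glycolytic,
    retinol-rich) and the interior disk labeled 2 (the inner mass — more
    oxidative). ``rim_free_fraction`` / ``core_free_fraction`` set the
    ground-truth free-NADH intensity fraction of each layer.

    Spectral abundances: retinol dominates the rim; the remaining weight in
    each layer is split between free and bound NADH according to the layer's
    free fraction, with a small FAD admixture in the core.
    """
    if not 0 < rim_thickness < outer_radius:
        raise ValueError("require 0 < rim_thickness < outer_radius")
    for name, f in (("rim", rim_free_fraction), ("core", core_free_fraction)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name}_free_fraction must lie in [0, 1], got {f}")
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    if outer_radius > min(cy, cx):
        raise ValueError(
            f"phantom radius {outer_radius} px does not fit a "
            f"{height}x{width} frame (max {min(cy, cx):.1f})"
        )

    yy, xx = np.mgrid[0:height, 0:width]
    r = np.hypot(yy - cy, xx - cx)
    inner_radius = outer_radius - rim_thickness
    labels = np.zeros((height, width), dtype=np.int32)
    labels[r <= outer_radius] = 1
    labels[r <= inner_radius] = 2

    free = np.zeros((height, width))
    free[labels == 1] = rim_free_fraction
    free[labels == 2] = core_free_fraction

    # abundance budget per layer; remainder (if any) is dark
    retinol = np.zeros_like(free)
    retinol[labels == 1] = rim_retinol
    retinol[labels == 2] = core_retinol
    fad = np.zeros_like(free)
    fad[labels == 2] = 0.10
    nadh_budget = np.clip(1.0 - retinol - fad, 0.0, 1.0)
    nadh_budget[labels == 0] = 0.0
    free_nadh = nadh_budget * free
    bound_nadh = nadh_budget * (1.0 - free)
    bound_nadh[labels == 0] = 0.0

    return OrganoidPhantom(
        label_image=labels,
        free_fraction_map=free,
        spectral_weight_maps={
            "retinol": retinol,
            "free-NADH": free_nadh,
            "bound-NADH": bound_nadh,
            "FAD": fad,
        },
        pixel_size=pixel_size,
        meta={
            "height": height,
            "width": width,
            "outer_radius": outer_radius,
            "rim_thickness": rim_thickness,
            "rim_free_fraction": rim_free_fraction,
            "core_free_fraction": core_free_fraction,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# decay simulation
# ---------------------------------------------------------------------------


def _wrapped_exp_histogram(tau: float, n_bins: int, rep_period: float) -> np.ndarray:
    """Bin-integrated, periodically wrapped mono-exponential, normalized to 1.

    The emission from a pulse train with period T is the wrap-around sum
    sum_m exp(-(t + m T)/tau); integrating over bin k gives weights
    proportional to exp(-t_k/tau) - exp(-t_{k+1}/tau), the wrap factor
    cancelling under normalization.
    """
    if tau <= 0:
        raise ValueError(f"lifetime must be positive, got {tau}")
    edges = np.linspace(0.0, rep_period, n_bins + 1)
    h = np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau)
    return h / h.sum()


def simulate_decay_cube(
    phantom: OrganoidPhantom,
    tau_free: float = 0.4,
    tau_bound: float = 3.4,
    photons_per_pixel: float = 1e4,
    n_bins: int = 256,
    rep_period: float = DEFAULT_REP_PERIOD_NS,
    noise: str = "none",
    seed: int = 0,
    background_photons: float = 0.0,
) -> DecayCube:
    """Simulate a FLIM acquisition of the phantom.

    Each foreground pixel's expected histogram is the free-fraction-weighted
    sum of two periodic mono-exponential decays (free and bound NADH) with
    ``photons_per_pixel`` expected photons; the free fraction is an
    *intensity* fraction, so it is exactly the quantity the phasor-chord
    projection recovers. Background pixels receive ``background_photons``
    expected counts spread uniformly (default 0).

    ``noise='poisson'`` draws integer counts with the given seed;
    ``noise='none'`` returns the real-valued expectation.
    """
    if not tau_free < tau_bound:
        raise ValueError("require tau_free < tau_bound")
    if photons_per_pixel <= 0:
        raise ValueError("photons_per_pixel must be positive")
    if n_bins < 16:
        raise ValueError("need at least 16 time bins")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    if tau_bound > rep_period / 2:
        warnings.warn(
            f"tau_bound={tau_bound} ns is large relative to the repetition "
            f"period {rep_period} ns; decays wrap substantially",
            stacklevel=2,
        )

    h_free = _wrapped_exp_histogram(tau_free, n_bins, rep_period)
    h_bound = _wrapped_exp_histogram(tau_bound, n_bins, rep_period)
    f = phantom.free_fraction_map[..., None]
    fg = phantom.foreground[..., None]
    expected = photons_per_pixel * fg * (f * h_free + (1.0 - f) * h_bound)
    if background_photons > 0:
        expected = expected + (~fg) * (background_photons / n_bins)

    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.float64)
    else:
        counts = expected

    return DecayCube(
        counts=counts,
        rep_period=rep_period,
        meta={
            "tau_free": tau_free,
            "tau_bound": tau_bound,
            "photons_per_pixel": photons_per_pixel,
            "noise": noise,
            "seed": seed,
            "pixel_size": phantom.pixel_size,
        },
    )


def make_reference_decay(
    tau_ref: float = 2.5,
    n_bins: int = 256,
    rep_period: float = DEFAULT_REP_PERIOD_NS,
    phase_offset: float = 0.0,
    modulation_scale: float = 1.0,
    seed: int = 0,
    frame_shape: tuple[int, int] = (32, 32),
    photons_per_pixel: float = 1e4,
    noise: str = "none",
) -> DecayCube:
    """Uniform-field reference decay for calibration (coumarin-6 style).

    A mono-exponential at ``tau_ref`` fills every pixel. An optional
    instrument distortion — rotation of the first-harmonic phasor by
    ``phase_offset`` radians and scaling of its modulus by
    ``modulation_scale`` — is injected identically at every pixel, so that
    the calibration stage has a known distortion to undo.

    The rotation is realized as a circular shift of the histogram by the
    whole number of time bins closest to the requested offset, which
    rotates the discrete phasor *exactly* by a multiple of the bin phase
    2*pi/n_bins; the offset actually applied is recorded in
    ``meta['applied_phase_offset']``. The modulation scales the histogram's
    AC component about its mean, which multiplies the phasor modulus
    exactly by ``modulation_scale`` and keeps counts positive for scales
    up to 1 (larger scales are clipped with a warning).
    """
    if modulation_scale <= 0:
        raise ValueError("modulation_scale must be positive")
    h = _wrapped_exp_histogram(tau_ref, n_bins, rep_period)

    applied_offset = 0.0
    if phase_offset != 0.0:
        bin_phase = 2.0 * np.pi / n_bins
        shift = int(np.round(phase_offset / bin_phase))
        applied_offset = shift * bin_phase
        # t_{k+shift} = t_k + shift*bin_width modulo the period, so rolling
        # multiplies the first harmonic by exp(i * shift * bin_phase)
        h = np.roll(h, shift)
    if modulation_scale != 1.0:
        mean = h.mean()
        h = mean + modulation_scale * (h - mean)
        if h.min() < 0:
            warnings.warn(
                "modulation_scale drove parts of the reference histogram "
                "negative; clipping breaks exact modulus scaling",
                stacklevel=2,
            )
            h = np.clip(h, 0.0, None)
        h = h / h.sum()

    expected = np.broadcast_to(h, (*frame_shape, n_bins)) * photons_per_pixel
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.float64)
    elif noise == "none":
        counts = np.array(expected)
    else:
        raise ValueError(f"unknown noise model {noise!r}")

    return DecayCube(
        counts=counts,
        rep_period=rep_period,
        meta={
            "tau_ref": tau_ref,
            "phase_offset": phase_offset,
            "applied_phase_offset": applied_offset,
            "modulation_scale": modulation_scale,
            "seed": seed,
            "reference": True,
        },
    )


# ---------------------------------------------------------------------------
# hyperspectral simulation
# ---------------------------------------------------------------------------


def default_channel_centers(n_channels: int = 32) -> np.ndarray:
    """Detector channel centers spanning 410-690 nm."""
    edges = np.linspace(410.0, 690.0, n_channels + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def gaussian_endmember(
    name: str,
    peak_nm: float,
    width_nm: float,
    channel_centers: np.ndarray | None = None,
) -> EndmemberSpectrum:
    """Gaussian emission profile on the detector channel grid."""
    if channel_centers is None:
        channel_centers = default_channel_centers()
    profile = np.exp(-0.5 * ((channel_centers - peak_nm) / width_nm) ** 2)
    return EndmemberSpectrum(name=name, emission=profile)


def default_endmembers(channel_centers: np.ndarray | None = None) -> list[EndmemberSpectrum]:
    """Endmember set matching the phantom's abundance maps.

    Peak positions follow the familiar autofluorescence landscape: NADH
    emission near 460 nm (free slightly red of bound), retinol near 490 nm,
    FAD near 530 nm. Widths are chosen for clear phasor separation.
    """
    return [
        gaussian_endmember("retinol", 490.0, 18.0, channel_centers),
        gaussian_endmember("free-NADH", 465.0, 35.0, channel_centers),
        gaussian_endmember("bound-NADH", 445.0, 30.0, channel_centers),
        gaussian_endmember("FAD", 530.0, 28.0, channel_centers),
    ]


def simulate_spectral_cube(
    phantom: OrganoidPhantom,
    endmembers: list[EndmemberSpectrum] | None = None,
    brightness: float = 1000.0,
    noise: str = "none",
    seed: int = 0,
    channel_centers: np.ndarray | None = None,
) -> SpectralCube:
    """Mix endmember spectra by the phantom's abundance maps.

    Per pixel: spectrum = brightness * sum_e abundance_e * emission_e.
    """
    if channel_centers is None:
        channel_centers = default_channel_centers()
    if endmembers is None:
        endmembers = default_endmembers(channel_centers)
    by_name = {e.name: e for e in endmembers}
    for name, m in phantom.spectral_weight_maps.items():
        if np.any(m > 0) and name not in by_name:
            raise ValueError(f"no endmember spectrum supplied for {name!r}")

    n_channels = len(channel_centers)
    expected = np.zeros((*phantom.shape, n_channels))
    for name, abundance in phantom.spectral_weight_maps.items():
        if name in by_name:
            expected += abundance[..., None] * by_name[name].emission
    expected *= brightness

    if noise == "poisson":
        rng = np.random.default_rng(seed)
        intensity = rng.poisson(expected).astype(np.float64)
    elif noise == "none":
        intensity = expected
    else:
        raise ValueError(f"unknown noise model {noise!r}")

    return SpectralCube(
        intensity=intensity,
        channel_centers=channel_centers,
        meta={
            "brightness": brightness,
            "noise": noise,
            "seed": seed,
            "endmembers": [e.name for e in endmembers],
            "pixel_size": phantom.pixel_size,
        },
    )


# ---------------------------------------------------------------------------
# qPCR table generation
# ---------------------------------------------------------------------------


def make_qpcr_table(
    n_genes: int = 4,
    groups: list[str] | None = None,
    log2_effects: dict[str, dict[str, float]] | None = None,
    nondetect_pattern: set[tuple[str, str]] | None = None,
    replicate_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    control_group: str = "D0",
    housekeeping_gene: str = "HK",
) -> QPCRTable:
    """Generate a Ct table whose ddCt analysis recovers known effects.

    ``log2_effects[group][gene]`` is the programmed log2 fold expression of
    that gene in that group relative to the control group; the generator
    writes Ct(group, gene) = base_gene - effect + group_shift + noise, with
    a per-group global shift that the housekeeping normalization must
    cancel. The control group and the housekeeping gene carry no effect.

    Cells listed in ``nondetect_pattern`` (group, gene) are flagged
    non-detected (NaN Ct, written as empty cells on export).
    """
    if groups is None:
        groups = [control_group, "M2", "M3"]
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} must be in groups")
    log2_effects = log2_effects or {}
    nondetect_pattern = nondetect_pattern or set()
    for g, per_gene in log2_effects.items():
        if housekeeping_gene in per_gene:
            raise ValueError("cannot inject an effect on the housekeeping gene")
        if g == control_group and any(v != 0 for v in per_gene.values()):
            raise ValueError("control group must carry zero effect")

    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1}" for i in range(n_genes)]
    base_ct = {g: c for g, c in zip(genes, rng.uniform(22.0, 30.0, n_genes))}
    base_ct[housekeeping_gene] = 18.0
    group_shift = {g: s for g, s in zip(groups, rng.uniform(-0.5, 0.5, len(groups)))}

    rows = []
    for group in groups:
        effects = log2_effects.get(group, {})
        for gene in [housekeeping_gene] + genes:
            effect = effects.get(gene, 0.0)
            for rep in range(1, n_replicates + 1):
                if (group, gene) in nondetect_pattern:
                    ct = np.nan
                else:
                    ct = base_ct[gene] - effect + group_shift[group]
                    if replicate_sd > 0:
                        ct += rng.normal(0.0, replicate_sd)
                    ct = float(np.clip(ct, 1.0, 39.5))
                rows.append(
                    {"group_id": group, "gene_id": gene, "replicate_id": rep, "ct": ct}
                )

    return QPCRTable(
        data=pd.DataFrame(rows),
        housekeeping_gene=housekeeping_gene,
        control_group=control_group,
        meta={"seed": seed, "replicate_sd": replicate_sd, "log2_effects": log2_effects},
    )
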