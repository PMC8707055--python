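"""End-to-end workflow stages binding the analysis modules together.

simulate -> FLIM metabolic map -> hyperspectral retinol map -> longitudinal
summary -> qPCR heatmap. Each stage is a plain function taking a
``RunConfig`` plus input paths, writing its outputs with a JSON manifest
(config hash, package version, parameters), and returning the paths it
wrote. The CLI wraps these functions without adding logic, so scripts and
tests can drive the identical code path.

Every stage is deterministic given config + seed, and no stage mutates its
inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as opio
from .flim import apply_calibration, decay_to_phasor, derive_calibration, median_filter_phasor
from .metabolic import (
    DEFAULT_AGE_BINS,
    colorize_metabolic,
    make_nadh_axis,
    outer_rim_mask,
    project_fb_ratio,
    project_to_axis,
    summarize_age_series,
)
from .qpcr import delta_delta_ct, heatmap_matrix, impute_nondetect
from .spectral import PhasorCursor, cursor_select, recolor_selection, spectrum_to_phasor, total_intensity_image
from .synth import (
    DEFAULT_REP_PERIOD_NS,
    make_organoid_phantom,
    make_qpcr_table,
    make_reference_decay,
    simulate_decay_cube,
    simulate_spectral_cube,
)

__all__ = ["RunConfig", "run_simulate", "run_flim", "run_hspec", "run_report", "run_qpcr"]

log = logging.getLogger("organoidphasor")


@dataclass
class RunConfig:
    """One run's acquisition and analysis parameters.

    Physical defaults mirror a standard two-photon FLIM/hyperspectral
    acquisition: 256 x 256 frame at 1.66 um/pixel, 80 MHz repetition
    (12.5 ns period), 256 time bins, 32 spectral channels over 410-690 nm.
    """

    # acquisition
    height: int = 256
    width: int = 256
    rep_period: float = DEFAULT_REP_PERIOD_NS
    n_bins: int = 256
    n_channels: int = 32
    pixel_size: float = 1.66
    # phantom
    outer_radius: float = 100.0
    rim_thickness: float = 15.0
    rim_free_fraction: float = 0.7
    core_free_fraction: float = 0.3
    photons_per_pixel: float = 1e4
    noise: str = "poisson"
    # analysis
    tau_free: float = 0.4
    tau_bound: float = 3.4
    tau_ref: float = 2.5
    harmonic: int = 1
    median_window: int = 3
    intensity_threshold: float | None = None
    rim_width: int = 10
    age_bins: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEFAULT_AGE_BINS)
    )
    cursors: list[dict] = field(default_factory=list)
    # provenance
    seed: int = 0
    version: str = __version__

    def __post_init__(self) -> None:
        for name in ("rep_period", "pixel_size", "photons_per_pixel", "tau_free",
                     "tau_bound", "tau_ref", "outer_radius", "rim_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if not self.tau_free < self.tau_bound:
            raise ValueError("config requires tau_free < tau_bound")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.rep_period

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        raw.pop("version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "age_bins" in raw:
            raw["age_bins"] = [tuple(b) for b in raw["age_bins"]]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        payload["age_bins"] = [list(b) for b in payload["age_bins"]]
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(out_dir: Path, stage: str, config: RunConfig, outputs: dict) -> Path:
    manifest = {
        "stage": stage,
        "config_hash": config.digest(),
        "version": config.version,
        "seed": config.seed,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    path = out_dir / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_simulate(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a full synthetic dataset: phantom, cubes, reference, qPCR CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("simulate: frame %dx%d seed %d", config.height, config.width, config.seed)

    phantom = make_organoid_phantom(
        height=config.height,
        width=config.width,
        outer_radius=config.outer_radius,
        rim_thickness=config.rim_thickness,
        rim_free_fraction=config.rim_free_fraction,
        core_free_fraction=config.core_free_fraction,
        seed=config.seed,
        pixel_size=config.pixel_size,
    )
    cube = simulate_decay_cube(
        phantom,
        tau_free=config.tau_free,
        tau_bound=config.tau_bound,
        photons_per_pixel=config.photons_per_pixel,
        n_bins=config.n_bins,
        rep_period=config.rep_period,
        noise=config.noise,
        seed=config.seed,
    )
    reference = make_reference_decay(
        tau_ref=config.tau_ref,
        n_bins=config.n_bins,
        rep_period=config.rep_period,
        seed=config.seed,
    )
    spectral = simulate_spectral_cube(phantom, noise=config.noise, seed=config.seed)
    qpcr = make_qpcr_table(seed=config.seed)

    outputs = {
        "phantom": opio.write_phantom(phantom, out_dir / "phantom.tif"),
        "decay_cube": opio.write_decay_cube(cube, out_dir / "decay.tif"),
        "reference": opio.write_decay_cube(reference, out_dir / "reference.tif"),
        "spectral_cube": opio.write_spectral_cube(spectral, out_dir / "spectral.tif"),
        "qpcr": opio.write_qpcr_table(qpcr, out_dir / "qpcr.csv"),
        "config": config.to_yaml(out_dir / "config.yaml"),
    }
    outputs["manifest"] = _write_manifest(out_dir, "simulate", config, outputs)
    return outputs


def analyze_flim(config: RunConfig, cube, reference):
    """Library-level FLIM chain: phasor -> calibrate -> filter -> project.

    Returns (metabolic_map, rim_mask, fb_ratio_scalar). The scalar f/b
    ratio comes from the rim region's phasor center of mass projected onto
    the free-bound axis.
    """
    field_raw = decay_to_phasor(cube, harmonic=config.harmonic)
    ref_field = decay_to_phasor(reference, harmonic=config.harmonic)
    cal = derive_calibration(ref_field, tau_ref=config.tau_ref)
    field_cal = apply_calibration(field_raw, cal)
    field_cal = median_filter_phasor(field_cal, window=config.median_window)
    axis = make_nadh_axis(config.omega, config.tau_free, config.tau_bound)
    mmap = project_to_axis(field_cal, axis)
    rim = outer_rim_mask(field_cal.intensity, rim_width=config.rim_width)
    ratio = project_fb_ratio(field_cal, axis, mask=rim)
    return mmap, rim, ratio


def run_flim(
    config: RunConfig,
    decay_path: str | Path,
    reference_path: str | Path,
    out_dir: str | Path,
    sample_id: str = "sample",
    age_days: float | None = None,
) -> dict[str, Path]:
    """FLIM stage: metabolic map, pseudo-color PNG, rim f/b ratio record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cube = opio.read_decay_cube(decay_path)
    reference = opio.read_decay_cube(reference_path)
    if not np.isclose(cube.rep_period, reference.rep_period):
        raise ValueError(
            f"repetition period mismatch: cube {cube.rep_period} ns vs "
            f"reference {reference.rep_period} ns"
        )
    log.info("flim: %s (rep period %.3f ns, %d bins)", decay_path, cube.rep_period, cube.n_bins)

    mmap, rim, ratio = analyze_flim(config, cube, reference)
    n_clamped = int(mmap.clamped_mask.sum())
    if n_clamped:
        log.warning("flim: %d pixels projected outside [0, 1] and were clamped", n_clamped)
    rgb, strip = colorize_metabolic(mmap)

    results_csv = out_dir / "fb_ratios.csv"
    row = pd.DataFrame(
        [{"sample_id": sample_id, "age_days": age_days, "fb_ratio": ratio}]
    )
    header = not results_csv.exists()
    row.to_csv(results_csv, mode="a", header=header, index=False)
    log.info("flim: rim f/b ratio %.4f for %s", ratio, sample_id)

    outputs = {
        "metabolic_map": opio.write_metabolic_map(mmap, out_dir / "metabolic_map.tif"),
        "overlay": opio.write_png(rgb, out_dir / "metabolic_overlay.png"),
        "colorbar": opio.write_png(strip, out_dir / "metabolic_colorbar.png"),
        "results": results_csv,
    }
    outputs["manifest"] = _write_manifest(out_dir, "flim", config, outputs)
    return outputs


def run_hspec(
    config: RunConfig, spectral_path: str | Path, out_dir: str | Path
) -> dict[str, Path]:
    """Hyperspectral stage: total intensity, cursor overlay, mask TIFF."""
    if not config.cursors:
        raise ValueError("hspec stage requires at least one configured cursor")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cube = opio.read_spectral_cube(spectral_path)
    log.info("hspec: %s (%d channels)", spectral_path, cube.n_channels)

    fieldv = spectrum_to_phasor(
        cube, harmonic=config.harmonic, intensity_threshold=config.intensity_threshold
    )
    cursor_cfg = config.cursors[0]
    cursor = PhasorCursor(
        center=tuple(cursor_cfg["center"]),
        radius=float(cursor_cfg["radius"]),
        label=cursor_cfg.get("label", "selection"),
        color=tuple(cursor_cfg.get("color", (255, 0, 0))),
    )
    mask = cursor_select(fieldv, cursor)
    if not mask.any():
        log.warning("hspec: cursor %r selected no pixels", cursor.label)
    overlay = recolor_selection(cube, mask, cursor)
    total = total_intensity_image(cube)
    peak = total.max()
    total_png = (255 * total / peak if peak > 0 else total).astype(np.uint8)

    import tifffile

    mask_path = out_dir / f"{cursor.label}_mask.tif"
    tifffile.imwrite(mask_path, mask.astype(np.uint8))
    outputs = {
        "total_intensity": opio.write_png(total_png, out_dir / "total_intensity.png"),
        "overlay": opio.write_png(overlay, out_dir / f"{cursor.label}_overlay.png"),
        "mask": mask_path,
    }
    outputs["manifest"] = _write_manifest(out_dir, "hspec", config, outputs)
    return outputs


def run_report(
    config: RunConfig, results_csv: str | Path, out_dir: str | Path
) -> dict[str, Path]:
    """Longitudinal stage: age-binned f/b summary CSV + boxplot figure."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = pd.read_csv(results_csv)
    if records.empty:
        raise ValueError(f"no f/b ratio records in {results_csv}")
    summary = summarize_age_series(records, age_bins=config.age_bins)
    log.info("report: %d records in %d age bins", len(records), len(summary.table))

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t = summary.table
    centers = 0.5 * (t["age_min"] + t["age_max"])
    widths = 0.6 * (t["age_max"] - t["age_min"])
    for _, r in t.iterrows():
        c = 0.5 * (r["age_min"] + r["age_max"])
        w = 0.3 * (r["age_max"] - r["age_min"])
        ax.add_patch(
            plt.Rectangle(
                (c - w, r["q25"]), 2 * w, r["q75"] - r["q25"],
                fill=False, edgecolor="k",
            )
        )
        ax.hlines(r["median"], c - w, c + w, color="k", lw=2)
        ax.errorbar(c, r["median"], yerr=r["whisker"], color="k", capsize=4, fmt="none")
    ax.set_xlim(t["age_min"].min() - 5, t["age_max"].max() + 5)
    lo = (t["median"] - t["whisker"]).min()
    hi = (t["median"] + t["whisker"]).max()
    pad = 0.1 * max(hi - lo, 1e-6)
    ax.set_ylim(min(lo, t["q25"].min()) - pad, max(hi, t["q75"].max()) + pad)
    ax.set_xlabel("age (days of differentiation)")
    ax.set_ylabel("f/b NADH ratio")
    fig.tight_layout()
    fig_path = out_dir / "fb_ratio_boxplot.png"
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)

    csv_path = out_dir / "age_series_summary.csv"
    summary.table.to_csv(csv_path, index=False)
    outputs = {"summary": csv_path, "figure": fig_path}
    outputs["manifest"] = _write_manifest(out_dir, "report", config, outputs)
    return outputs


def run_qpcr(
    config: RunConfig, qpcr_csv: str | Path, out_dir: str | Path
) -> dict[str, Path]:
    """qPCR stage: impute non-detects, ddCt, heatmap."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = opio.read_qpcr_table(qpcr_csv)
    imputed = impute_nondetect(table)
    if imputed.meta.get("n_imputed"):
        log.info("qpcr: imputed %d non-detected wells at Ct 40", imputed.meta["n_imputed"])
    matrix = delta_delta_ct(imputed)
    ordered, fig = heatmap_matrix(matrix)

    csv_path = out_dir / "log2_fold_expression.csv"
    ordered.log2_fe.to_csv(csv_path)
    fig_path = out_dir / "qpcr_heatmap.png"
    fig.savefig(fig_path, dpi=150)
    import matplotlib.pyplot as plt

    plt.close(fig)
    outputs = {"matrix": csv_path, "heatmap": fig_path}
    outputs["manifest"] = _write_manifest(out_dir, "qpcr", config, outputs)
    return outputs
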