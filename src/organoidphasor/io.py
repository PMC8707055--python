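"""File I/O: multi-page TIFF cubes with JSON sidecars, CSV tables.

Conventions: image origin top-left, (row, column) = (y, x), 0-based; cubes
are written one page per time bin / spectral channel; every array file is
accompanied by a ``<name>.json`` sidecar carrying physical metadata
(repetition period, bin width, channel centers, pixel size, seed). qPCR
tables are CSV with columns group_id, gene_id, replicate_id, ct — an empty
ct cell means non-detected — plus a sidecar naming the housekeeping gene
and control group.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flim import CalibrationFactors, PhasorField
from .metabolic import MetabolicMap
from .synth import DecayCube, OrganoidPhantom, QPCRTable, SpectralCube

__all__ = [
    "write_decay_cube",
    "read_decay_cube",
    "write_spectral_cube",
    "read_spectral_cube",
    "write_phantom",
    "read_phantom",
    "write_phasor_field",
    "read_phasor_field",
    "write_metabolic_map",
    "write_calibration",
    "read_calibration",
    "write_qpcr_table",
    "read_qpcr_table",
    "write_png",
]

_AXES_NOTE = {"origin": "top-left", "index_order": "(y, x), 0-based"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_decay_cube(cube: DecayCube, path: str | Path) -> Path:
    """Write counts as a multi-page TIFF (one page per time bin) + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.moveaxis(cube.counts, 2, 0).astype(np.float32))
    _write_json(
        _sidecar(path),
        {
            "kind": "decay_cube",
            "rep_period_ns": cube.rep_period,
            "bin_width_ns": cube.bin_width,
            "n_bins": cube.n_bins,
            "axes": _AXES_NOTE,
            "meta": cube.meta,
        },
    )
    return path


def read_decay_cube(path: str | Path) -> DecayCube:
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot parse TIFF decay cube {path}: {exc}") from exc
    side = json.loads(_sidecar(path).read_text())
    if side.get("kind") != "decay_cube":
        raise ValueError(f"{path} sidecar does not describe a decay cube")
    return DecayCube(
        counts=np.moveaxis(np.asarray(pages, dtype=np.float64), 0, 2),
        rep_period=side["rep_period_ns"],
        meta=side.get("meta", {}),
    )


def write_spectral_cube(cube: SpectralCube, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.moveaxis(cube.intensity, 2, 0).astype(np.float32))
    _write_json(
        _sidecar(path),
        {
            "kind": "spectral_cube",
            "channel_centers_nm": cube.channel_centers,
            "axes": _AXES_NOTE,
            "meta": cube.meta,
        },
    )
    return path


def read_spectral_cube(path: str | Path) -> SpectralCube:
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot parse TIFF spectral cube {path}: {exc}") from exc
    side = json.loads(_sidecar(path).read_text())
    if side.get("kind") != "spectral_cube":
        raise ValueError(f"{path} sidecar does not describe a spectral cube")
    return SpectralCube(
        intensity=np.moveaxis(np.asarray(pages, dtype=np.float64), 0, 2),
        channel_centers=np.asarray(side["channel_centers_nm"], dtype=float),
        meta=side.get("meta", {}),
    )


def write_phantom(phantom: OrganoidPhantom, path: str | Path) -> Path:
    """Ground-truth maps as a multi-plane TIFF: labels, free fraction, abundances."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = sorted(phantom.spectral_weight_maps)
    planes = [
        phantom.label_image.astype(np.float32),
        phantom.free_fraction_map.astype(np.float32),
    ] + [phantom.spectral_weight_maps[n].astype(np.float32) for n in names]
    tifffile.imwrite(path, np.stack(planes))
    _write_json(
        _sidecar(path),
        {
            "kind": "organoid_phantom",
            "planes": ["labels", "free_fraction"] + names,
            "pixel_size_um": phantom.pixel_size,
            "axes": _AXES_NOTE,
            "meta": phantom.meta,
        },
    )
    return path


def read_phantom(path: str | Path) -> OrganoidPhantom:
    path = Path(path)
    planes = np.asarray(tifffile.imread(path), dtype=np.float64)
    side = json.loads(_sidecar(path).read_text())
    if side.get("kind") != "organoid_phantom":
        raise ValueError(f"{path} sidecar does not describe a phantom")
    names = side["planes"][2:]
    return OrganoidPhantom(
        label_image=planes[0].astype(np.int32),
        free_fraction_map=planes[1],
        spectral_weight_maps={n: planes[2 + i] for i, n in enumerate(names)},
        pixel_size=side.get("pixel_size_um", 1.66),
        meta=side.get("meta", {}),
    )


def write_phasor_field(fieldv: PhasorField, path: str | Path) -> Path:
    """3-plane TIFF (g, s, intensity) + sidecar (omega, harmonic, calibrated)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        np.stack([fieldv.g, fieldv.s, fieldv.intensity]).astype(np.float32),
    )
    _write_json(
        _sidecar(path),
        {
            "kind": "phasor_field",
            "omega_rad_per_ns": fieldv.omega,
            "harmonic": fieldv.harmonic,
            "calibrated": fieldv.calibrated,
            "axes": _AXES_NOTE,
            "meta": fieldv.meta,
        },
    )
    return path


def read_phasor_field(path: str | Path) -> PhasorField:
    path = Path(path)
    planes = np.asarray(tifffile.imread(path), dtype=np.float64)
    side = json.loads(_sidecar(path).read_text())
    if side.get("kind") != "phasor_field":
        raise ValueError(f"{path} sidecar does not describe a phasor field")
    return PhasorField(
        g=planes[0],
        s=planes[1],
        intensity=planes[2],
        omega=side["omega_rad_per_ns"],
        harmonic=side["harmonic"],
        calibrated=side["calibrated"],
        meta=side.get("meta", {}),
    )


def write_metabolic_map(mmap: MetabolicMap, path: str | Path) -> Path:
    """2-plane TIFF (F1, intensity) + sidecar with axis lifetimes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.stack([mmap.f1, mmap.intensity]).astype(np.float32))
    _write_json(
        _sidecar(path),
        {
            "kind": "metabolic_map",
            "tau_free_ns": mmap.axis.tau_free,
            "tau_bound_ns": mmap.axis.tau_bound,
            "omega_rad_per_ns": mmap.axis.omega,
            "n_clamped": int(mmap.clamped_mask.sum()),
            "axes": _AXES_NOTE,
            "meta": mmap.meta,
        },
    )
    return path


def write_calibration(cal: CalibrationFactors, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_json(
        path,
        {
            "kind": "calibration",
            "phase_correction_rad": cal.phase_correction,
            "modulation_correction": cal.modulation_correction,
            "tau_ref_ns": cal.tau_ref,
            "omega_rad_per_ns": cal.omega,
        },
    )
    return path


def read_calibration(path: str | Path) -> CalibrationFactors:
    side = json.loads(Path(path).read_text())
    return CalibrationFactors(
        phase_correction=side["phase_correction_rad"],
        modulation_correction=side["modulation_correction"],
        tau_ref=side["tau_ref_ns"],
        omega=side["omega_rad_per_ns"],
    )


def write_qpcr_table(table: QPCRTable, path: str | Path) -> Path:
    """CSV with an empty ct cell for non-detected wells + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=False)
    _write_json(
        _sidecar(path),
        {
            "kind": "qpcr_table",
            "housekeeping_gene": table.housekeeping_gene,
            "control_group": table.control_group,
            "meta": table.meta,
        },
    )
    return path


def read_qpcr_table(path: str | Path) -> QPCRTable:
    path = Path(path)
    data = pd.read_csv(path, dtype={"group_id": str, "gene_id": str})
    side = json.loads(_sidecar(path).read_text())
    if side.get("kind") != "qpcr_table":
        raise ValueError(f"{path} sidecar does not describe a qPCR table")
    return QPCRTable(
        data=data,
        housekeeping_gene=side["housekeeping_gene"],
        control_group=side["control_group"],
        meta=side.get("meta", {}),
    )


def write_png(image: np.ndarray, path: str | Path) -> Path:
    """Write a uint8 grayscale or RGB image as PNG."""
    from PIL import Image

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image).save(path)
    return path
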