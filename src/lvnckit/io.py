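"""File formats and run configuration.

Conventions: slice images are 8-bit grayscale PNG (or NIfTI), masks are
indexed PNG whose palette indices are the class labels {0 background, 1 EL,
2 IC, 3 T}, detector triplets and tabular reports are UTF-8 CSV with a
header and '.' decimals, machine-readable reports are JSON, and run
configuration is YAML.  Everything round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .cleaning import QCTriplet

__all__ = [
    "MaskFormatError",
    "SchemaError",
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
    "read_triplets",
    "write_triplets",
    "write_report",
    "write_cohort_manifest",
    "RunConfig",
    "load_config",
]

#: RGB palette used for indexed mask PNGs (background, EL, IC, T).
MASK_PALETTE = [(0, 0, 0), (0, 160, 60), (40, 90, 220), (235, 200, 40)]


class MaskFormatError(ValueError):
    """Raised for mask files with labels outside {0, 1, 2, 3}."""


class SchemaError(ValueError):
    """Raised for tabular files that miss required columns."""


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a {0..3} label grid as an indexed (palette) PNG."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise MaskFormatError("mask must be 2-D")
    if mask.min() < 0 or mask.max() > 3:
        raise MaskFormatError("mask labels must lie in {0, 1, 2, 3}")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = [v for rgb in MASK_PALETTE for v in rgb]
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(Path(path), format="PNG")


def read_mask(path: str | Path) -> np.ndarray:
    """Read an indexed PNG back into a uint8 label grid."""
    img = Image.open(Path(path))
    if img.mode != "P":
        img = img.convert("P")
    mask = np.asarray(img, dtype=np.uint8)
    if mask.max() > 3:
        raise MaskFormatError(f"{path}: labels outside {{0..3}}")
    return mask


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 8-bit grayscale PNG or NIfTI."""
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if path.name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(image.astype(np.float32), affine=np.eye(4)), path)
        return
    data = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path, format="PNG")


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG (rescaled to [0, 1]) or a NIfTI slice."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        data = np.asanyarray(nib.load(path).dataobj, dtype=float)
        return np.squeeze(data)
    img = Image.open(path).convert("L")
    return np.asarray(img, dtype=float) / 255.0


_TRIPLET_COLUMNS = ["slice_id", "patient_id", "group", "conf_valid", "conf_open", "area_frac"]


def write_triplets(path: str | Path, rows: list[dict]) -> None:
    """Write QC triplet records with the canonical column order."""
    df = pd.DataFrame(rows, columns=_TRIPLET_COLUMNS)
    df.to_csv(path, index=False)


def read_triplets(path: str | Path) -> list[tuple[str, str, QCTriplet]]:
    """Read a triplet CSV into (slice_id, group, triplet) records.

    An empty file with a valid header yields an empty list; missing
    columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRIPLET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return [
        (
            str(r.slice_id),
            str(r.group),
            QCTriplet(float(r.conf_valid), float(r.conf_open), float(r.area_frac)),
        )
        for r in df.itertuples()
    ]


def write_report(path: str | Path, report: Any) -> None:
    """Write a report object (dataclass with to_dict, or mapping) as JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_cohort_manifest(path: str | Path, rows: list[dict]) -> None:
    """Cohort manifest CSV: patient_id, group, slice_path, mask_path."""
    pd.DataFrame(rows, columns=["patient_id", "group", "slice_path", "mask_path"]).to_csv(
        path, index=False
    )


# -- run configuration -------------------------------------------------------

_CONFIG_SECTIONS = {
    "seed": int,
    "paths": dict,
    "model": dict,
    "train": dict,
    "clean": dict,
    "roi": dict,
    "synth": dict,
}


@dataclass
class RunConfig:
    """Validated YAML run configuration; unknown keys are rejected."""

    seed: int = 0
    paths: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    clean: dict = field(default_factory=dict)
    roi: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config, rejecting unknown top-level keys."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config must be a YAML mapping")
    unknown = set(raw) - set(_CONFIG_SECTIONS)
    if unknown:
        raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)
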