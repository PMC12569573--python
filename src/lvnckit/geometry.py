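"""Contour and bounding-box utilities on segmentation masks.

Detection labels for the LV are derived from ground-truth masks: the largest
connected component of the requested classes is located, its outer contour
extracted, and a tight axis-aligned box built around it.  Boxes use the
half-open pixel convention — a pixel at (r, c) occupies [r, r+1) x [c, c+1) —
so a box's width and height equal pixel counts and its centre is
``min + extent / 2``.  Normalised (YOLO-style) labels are fractions of the
image dimensions, written as ``class_id x y width height`` with 6 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "BBox",
    "YoloLabel",
    "NoForegroundError",
    "largest_contour",
    "largest_component",
    "bbox_from_mask",
    "to_yolo_label",
    "from_yolo_label",
    "write_yolo_labels",
    "read_yolo_labels",
    "select_phases",
]


class NoForegroundError(ValueError):
    """Raised when a mask holds no pixel of the requested classes."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned pixel-space box: centre (cx, cy) and extent (w, h)."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box extent must be positive")

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class YoloLabel:
    """Normalised detection label; all fractions lie in [0, 1]."""

    class_id: int
    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValueError("class_id must be non-negative")
        for name in ("x", "y", "width", "height"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _class_mask(mask: np.ndarray, class_set: Iterable[int]) -> np.ndarray:
    mask = np.asarray(mask)
    return np.isin(mask, list(class_set))


def largest_component(mask: np.ndarray, class_set: Iterable[int]) -> np.ndarray:
    """Boolean image of the largest 8-connected component of ``class_set``.

    Ties on area are broken by the smallest (row, column) of each
    component's topmost-then-leftmost pixel.
    """
    fg = _class_mask(mask, class_set)
    if not fg.any():
        raise NoForegroundError("mask holds no pixel of the requested classes")
    labels = measure.label(fg, connectivity=2)
    best_label, best_key = 0, None
    for region in measure.regionprops(labels):
        rows, cols = np.nonzero(labels == region.label)
        order = np.lexsort((cols, rows))
        anchor = (int(rows[order[0]]), int(cols[order[0]]))
        key = (-region.area, anchor)
        if best_key is None or key < best_key:
            best_key, best_label = key, region.label
    return labels == best_label


def largest_contour(mask: np.ndarray, class_set: Iterable[int]) -> np.ndarray:
    """Outer contour of the largest component, as an (N, 2) array of (row, col).

    Holes inside the component (e.g. the cavity inside an annular compact
    layer) are filled before tracing, so the returned polygon is the outer
    boundary and encloses any holes.
    """
    comp = largest_component(mask, class_set)
    filled = ndimage.binary_fill_holes(comp)
    padded = np.pad(filled.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    outer = max(contours, key=lambda c: len(c))
    return outer - 1.0  # undo padding offset


def bbox_from_mask(mask: np.ndarray, class_set: Iterable[int]) -> BBox:
    """Tight box around the largest component of ``class_set``."""
    comp = largest_component(mask, class_set)
    rows, cols = np.nonzero(comp)
    r0, r1 = int(rows.min()), int(rows.max())
    c0, c1 = int(cols.min()), int(cols.max())
    w = float(c1 - c0 + 1)
    h = float(r1 - r0 + 1)
    return BBox(cx=c0 + w / 2.0, cy=r0 + h / 2.0, w=w, h=h)


def to_yolo_label(box: BBox, img_w: int, img_h: int, class_id: int = 0) -> YoloLabel:
    """Normalise a pixel-space box by the image dimensions."""
    if img_w <= 0 or img_h <= 0:
        raise ValueError("image dimensions must be positive")
    return YoloLabel(
        class_id=class_id,
        x=box.cx / img_w,
        y=box.cy / img_h,
        width=box.w / img_w,
        height=box.h / img_h,
    )


def from_yolo_label(label: YoloLabel, img_w: int, img_h: int) -> BBox:
    """Inverse of :func:`to_yolo_label`."""
    if img_w <= 0 or img_h <= 0:
        raise ValueError("image dimensions must be positive")
    return BBox(
        cx=label.x * img_w,
        cy=label.y * img_h,
        w=label.width * img_w,
        h=label.height * img_h,
    )


def write_yolo_labels(path: str | Path, labels: Sequence[YoloLabel]) -> None:
    """Write one detection per line: ``class_id x y width height`` (6 dp)."""
    lines = [
        f"{lb.class_id} {lb.x:.6f} {lb.y:.6f} {lb.width:.6f} {lb.height:.6f}"
        for lb in labels
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path: str | Path) -> list[YoloLabel]:
    labels = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        cid, x, y, w, h = line.split()
        labels.append(YoloLabel(int(cid), float(x), float(y), float(w), float(h)))
    return labels


def select_phases(frame_boxes: Sequence[BBox]) -> tuple[int, int]:
    """Pick the tele-diastolic and tele-systolic frames of a cine series.

    The most expanded LV (largest cavity box area) marks end-diastole and the
    least expanded marks end-systole.  Ties resolve to the lowest index.

    Returns ``(diastole_index, systole_index)``.
    """
    if not frame_boxes:
        raise ValueError("frame list must be non-empty")
    areas = [b.area for b in frame_boxes]
    return int(np.argmax(areas)), int(np.argmin(areas))
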