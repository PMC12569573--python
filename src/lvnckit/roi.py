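"""Detector-guided ROI construction for the segmentation network.

A detector proposes a box around the LV with confidence ``prob``.  The crop
side is inflated by how unsure the detector was,

    l_resize = max(w_roi, h_roi) * (1 + (1 - prob)),

so weakly detected ventricles get more context.  The square crop (zero-padded
at image borders) is converted to a single grayscale channel, resized to a
standard side (default 800 px) and z-score normalised.  Masks follow the same
geometric path with nearest-neighbour resampling so labels stay categorical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .geometry import BBox

__all__ = [
    "Detection",
    "expand_roi",
    "crop_square",
    "to_grayscale",
    "standardize",
    "preprocess_slice",
    "preprocess_pair",
]

DEFAULT_OUT_SIZE = 800


@dataclass(frozen=True)
class Detection:
    """A detector's box proposal and its confidence."""

    box: BBox
    prob: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob <= 1.0):
            raise ValueError("prob must lie in [0, 1]")


def expand_roi(det: Detection) -> float:
    """Confidence-adjusted side length of the square ROI (pixels).

    Equals ``max(w, h)`` at full confidence and grows linearly to twice that
    at zero confidence.
    """
    return max(det.box.w, det.box.h) * (1.0 + (1.0 - det.prob))


def crop_square(
    image: np.ndarray,
    center: tuple[float, float],
    side: float,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Square crop of ``side`` pixels centred at (cx, cy), padded outside.

    ``side`` is rounded to the nearest integer; regions falling outside the
    source image are filled with ``pad_value``.
    """
    image = np.asarray(image)
    s = max(1, int(round(side)))
    cx, cy = center
    r0 = int(round(cy - s / 2.0))
    c0 = int(round(cx - s / 2.0))
    out = np.full((s, s), pad_value, dtype=image.dtype)
    src_r0, src_r1 = max(r0, 0), min(r0 + s, image.shape[0])
    src_c0, src_c1 = max(c0, 0), min(c0 + s, image.shape[1])
    if src_r0 < src_r1 and src_c0 < src_c1:
        out[src_r0 - r0 : src_r1 - r0, src_c0 - c0 : src_c1 - c0] = image[
            src_r0:src_r1, src_c0:src_c1
        ]
    return out


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a trailing channel axis by averaging; pass 2-D through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3:
        return image.mean(axis=-1)
    raise ValueError("expected a 2-D image or an H x W x C array")


def standardize(image: np.ndarray, out_size: int = DEFAULT_OUT_SIZE) -> np.ndarray:
    """Resize (bilinear) to ``out_size`` square and z-score normalise.

    A constant input has no meaningful z-score and maps to all zeros.
    """
    image = to_grayscale(image)
    resized = resize(
        image, (out_size, out_size), order=1, preserve_range=True, anti_aliasing=False
    )
    std = resized.std()
    if std < 1e-12:
        return np.zeros((out_size, out_size), dtype=float)
    return (resized - resized.mean()) / std


def preprocess_slice(
    image: np.ndarray,
    det: Detection,
    out_size: int = DEFAULT_OUT_SIZE,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Full ROI pipeline: expand, crop, grayscale, resize, z-score."""
    side = expand_roi(det)
    crop = crop_square(to_grayscale(image), (det.box.cx, det.box.cy), side, pad_value)
    return standardize(crop, out_size)


def preprocess_pair(
    image: np.ndarray,
    mask: np.ndarray,
    det: Detection,
    out_size: int = DEFAULT_OUT_SIZE,
    pad_value: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply identical ROI geometry to an image and its label mask.

    The image goes through the bilinear + z-score path; the mask is cropped
    with background padding and resized with nearest-neighbour resampling so
    the output stays a valid {0..3} label grid.
    """
    side = expand_roi(det)
    center = (det.box.cx, det.box.cy)
    img_out = standardize(
        crop_square(to_grayscale(image), center, side, pad_value), out_size
    )
    mask_crop = crop_square(np.asarray(mask), center, side, 0)
    mask_out = resize(
        mask_crop.astype(float),
        (out_size, out_size),
        order=0,
        preserve_range=True,
        anti_aliasing=False,
    ).astype(mask_crop.dtype)
    return img_out, mask_out
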