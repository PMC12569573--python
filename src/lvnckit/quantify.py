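"""Trabecular-volume quantification and segmentation evaluation.

The clinical quantity of interest is the trabecular volume percentage

    TV% = 100 * T / (T + EL)

where ``T`` is the volume of the trabeculated (non-compacted) myocardium and
``EL`` the volume of the compacted outer wall.  Volumes are approximated by
summing per-slice segmented areas over a patient's short-axis stack; the
inner cavity (blood pool) is excluded from the wall-volume denominator.
A patient whose TV% exceeds 27.4 % is flagged as LVNC.

Mask label convention throughout the package:
0 = background, 1 = external/compact layer (EL), 2 = inner cavity (IC),
3 = trabeculae (T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LVNC_TV_THRESHOLD",
    "AreaBreakdown",
    "DiceReport",
    "class_areas",
    "tv_percent",
    "patient_tv",
    "classify_lvnc",
    "dice",
    "evaluate",
]

#: Validated TV% decision threshold for LVNC (strict ">").
LVNC_TV_THRESHOLD = 27.4

BACKGROUND, EXTERNAL_LAYER, INNER_CAVITY, TRABECULAE = 0, 1, 2, 3


class UndefinedQuantityError(ZeroDivisionError):
    """Raised when TV% is requested for an empty ventricular wall."""


@dataclass(frozen=True)
class AreaBreakdown:
    """Per-class segmented area of one slice (pixel^2 times spacing^2)."""

    area_el: float
    area_ic: float
    area_t: float

    def __post_init__(self) -> None:
        if min(self.area_el, self.area_ic, self.area_t) < 0:
            raise ValueError("areas must be non-negative")


@dataclass
class DiceReport:
    """Per-class and macro-average Dice, overall and per patient group."""

    dice_el: float
    dice_ic: float
    dice_t: float
    average: float
    grouped: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


def class_areas(mask: np.ndarray, spacing: float = 1.0) -> AreaBreakdown:
    """Per-class areas of a segmentation mask.

    Parameters
    ----------
    mask
        2-D integer label grid with values in {0, 1, 2, 3}.
    spacing
        Isotropic pixel spacing (mm/pixel); areas scale with ``spacing**2``.
        The default of 1 reports plain pixel counts.
    """
    mask = np.asarray(mask)
    factor = float(spacing) ** 2
    return AreaBreakdown(
        area_el=float(np.count_nonzero(mask == EXTERNAL_LAYER)) * factor,
        area_ic=float(np.count_nonzero(mask == INNER_CAVITY)) * factor,
        area_t=float(np.count_nonzero(mask == TRABECULAE)) * factor,
    )


def tv_percent(trab: float, compact: float) -> float:
    """Trabecular volume as a percentage of total wall volume.

    ``100 * trab / (trab + compact)``; raises :class:`UndefinedQuantityError`
    when the wall is empty (``trab + compact == 0``).
    """
    total = trab + compact
    if total <= 0:
        raise UndefinedQuantityError("TV% undefined: empty ventricular wall")
    return 100.0 * trab / total

def patient_tv(masks: Sequence[np.ndarray], spacing: float = 1.0) -> float:
    """Patient-level TV% from summed per-slice areas."""
    breakdowns = [class_areas(m, spacing) for m in masks]
    return tv_percent(
        sum(b.area_t for b in breakdowns), sum(b.area_el for b in breakdowns)
    )


def classify_lvnc(tv: float, threshold: float = LVNC_TV_THRESHOLD) -> bool:
    """LVNC decision: strictly greater than the threshold flags disease."""
    return tv > threshold


def dice(pred: np.ndarray, truth: np.ndarray, class_id: int) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) for one class; both-empty -> 1."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    a = pred == class_id
    b = truth == class_id
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / denom


_FOREGROUND = {"el": EXTERNAL_LAYER, "ic": INNER_CAVITY, "t": TRABECULAE}


def _mean_dice(preds: Sequence[np.ndarray], truths: Sequence[np.ndarray]) -> dict:
    out = {}
    for name, cid in _FOREGROUND.items():
        out[f"dice_{name}"] = float(
            np.mean([dice(p, t, cid) for p, t in zip(preds, truths)])
        )
    out["average"] = float(np.mean([out[f"dice_{n}"] for n in _FOREGROUND]))
    return out


def evaluate(
    preds: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    groups: Sequence[str] | None = None,
) -> DiceReport:
    """Slice-macro-averaged Dice per foreground class, overall and by group.

    ``average`` is the arithmetic mean of the EL, IC and T Dice values;
    the background class is never included.
    """
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")
    if not preds:
        raise ValueError("nothing to evaluate")
    overall = _mean_dice(list(preds), list(truths))
    grouped: dict[str, dict[str, float]] = {}
    if groups is not None:
        if len(groups) != len(preds):
            raise ValueError("groups must align with preds")
        for g in sorted(set(groups)):
            idx = [i for i, gi in enumerate(groups) if gi == g]
            grouped[g] = _mean_dice([preds[i] for i in idx], [truths[i] for i in idx])
    return DiceReport(
        dice_el=overall["dice_el"],
        dice_ic=overall["dice_ic"],
        dice_t=overall["dice_t"],
        average=overall["average"],
        grouped=grouped,
    )
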