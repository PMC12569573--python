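"""Rule-based quality control of short-axis MRI slices.

Each slice is summarised by a detector triplet
``(conf_valid, conf_open, area)``:

* ``conf_valid`` — confidence that a well-resolved inner cavity was detected,
* ``conf_open`` — confidence that the compact ring is open ("No Ring" slice),
* ``area`` — the detected cavity bounding-box area as a fraction of the image.

A two-stage linear cascade decides keep/discard:

Stage 1 discards a slice when ``conf_open - 5.526 * conf_valid > -4.3``
(high open-ring confidence, or a weakly detected cavity).  Stage 2 keeps
slices with ``conf_valid >= 0.88``, rejects those below ``0.83``, and inside
the band ``[0.83, 0.88)`` applies a negative-slope line so that lower cavity
confidence needs a larger cavity area to survive (small, artefact-prone
cavities are purged).  Patient TV% is recomputed over the surviving slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .quantify import patient_tv

__all__ = [
    "CleanConfig",
    "QCTriplet",
    "Decision",
    "CleanReport",
    "stage1_discard",
    "stage2_keep",
    "stage2_line",
    "clean_slice",
    "clean_decisions",
    "clean_dataset",
    "readjust_tv",
]


@dataclass(frozen=True)
class QCTriplet:
    """One slice's QC record (Conf-Valid-IC, Conf-Open-IC, Area-bbox-Valid-IC)."""

    conf_valid: float
    conf_open: float
    area: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.conf_valid <= 1.0):
            raise ValueError("conf_valid must lie in [0, 1]")
        if not (0.0 <= self.conf_open <= 1.0):
            raise ValueError("conf_open must lie in [0, 1]")
        if self.area < 0.0:
            raise ValueError("area must be non-negative")


@dataclass(frozen=True)
class CleanConfig:
    """Coefficients and thresholds of the two-stage cleaning cascade.

    ``stage2_slope``/``stage2_intercept`` default to the line through the two
    anchors (keep_threshold, 0) and (reject_threshold, area_ref): required
    area is zero at full confidence and ``area_ref`` at the band's low edge.
    """

    slope1: float = 5.526
    intercept1: float = -4.3
    keep_threshold: float = 0.88
    reject_threshold: float = 0.83
    area_ref: float = 0.02
    stage2_slope: float | None = None
    stage2_intercept: float | None = None

    def __post_init__(self) -> None:
        if self.reject_threshold >= self.keep_threshold:
            raise ValueError("reject_threshold must be below keep_threshold")
        if self.slope1 <= 0:
            raise ValueError("slope1 must be positive")
        if self.area_ref <= 0:
            raise ValueError("area_ref must be positive")
        if (self.stage2_slope is None) != (self.stage2_intercept is None):
            raise ValueError("override both stage-2 coefficients or neither")


class Decision(str, Enum):
    KEEP = "keep"
    DISCARD_STAGE1 = "discard_stage1"
    DISCARD_STAGE2 = "discard_stage2"


@dataclass
class CleanReport:
    """Partition of slice ids into keep / stage-1 discard / stage-2 discard."""

    kept: list[str]
    discarded_stage1: list[str]
    discarded_stage2: list[str]
    per_group_discard_counts: dict[str, int]

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.discarded_stage1) + len(self.discarded_stage2)

    def to_dict(self) -> dict:
        return {
            "kept": list(self.kept),
            "discarded_stage1": list(self.discarded_stage1),
            "discarded_stage2": list(self.discarded_stage2),
            "per_group_discard_counts": dict(self.per_group_discard_counts),
        }


def stage1_discard(t: QCTriplet, cfg: CleanConfig = CleanConfig()) -> bool:
    """Stage-1 rule: discard iff conf_open - slope1*conf_valid > intercept1.

    The inequality is strict; a slice exactly on the boundary is retained
    for stage 2.
    """
    return t.conf_open - cfg.slope1 * t.conf_valid > cfg.intercept1


def stage2_line(conf_valid: float, cfg: CleanConfig = CleanConfig()) -> float:
    """Minimum cavity-area fraction required at a given confidence (stage 2).

    Defined as the line through (keep_threshold, 0) and (reject_threshold,
    area_ref), evaluated in two-point form unless explicit coefficients
    override it.
    """
    if cfg.stage2_slope is not None:
        return cfg.stage2_slope * conf_valid + cfg.stage2_intercept
    return (
        cfg.area_ref
        * (cfg.keep_threshold - conf_valid)
        / (cfg.keep_threshold - cfg.reject_threshold)
    )


def stage2_keep(t: QCTriplet, cfg: CleanConfig = CleanConfig()) -> bool:
    """Stage-2 rule for slices that survived stage 1.

    Keep when ``conf_valid >= keep_threshold``; reject when below
    ``reject_threshold``; inside the band keep iff the cavity area clears the
    negative-slope line.
    """
    if t.conf_valid >= cfg.keep_threshold:
        return True
    if t.conf_valid < cfg.reject_threshold:
        return False
    return t.area >= stage2_line(t.conf_valid, cfg)


def clean_slice(t: QCTriplet, cfg: CleanConfig = CleanConfig()) -> Decision:
    """Full cascade decision for one slice."""
    if stage1_discard(t, cfg):
        return Decision.DISCARD_STAGE1
    return Decision.KEEP if stage2_keep(t, cfg) else Decision.DISCARD_STAGE2


def clean_decisions(
    conf_valid: np.ndarray,
    conf_open: np.ndarray,
    area: np.ndarray,
    cfg: CleanConfig = CleanConfig(),
) -> np.ndarray:
    """Vectorised cascade over parallel triplet arrays.

    Returns an integer array: 0 = keep, 1 = stage-1 discard, 2 = stage-2
    discard (identical semantics to :func:`clean_slice` element-wise).
    """
    conf_valid = np.asarray(conf_valid, dtype=float)
    conf_open = np.asarray(conf_open, dtype=float)
    area = np.asarray(area, dtype=float)
    s1 = conf_open - cfg.slope1 * conf_valid > cfg.intercept1
    if cfg.stage2_slope is not None:
        required = cfg.stage2_slope * conf_valid + cfg.stage2_intercept
    else:
        required = (
            cfg.area_ref
            * (cfg.keep_threshold - conf_valid)
            / (cfg.keep_threshold - cfg.reject_threshold)
        )
    keep2 = (conf_valid >= cfg.keep_threshold) | (
        (conf_valid >= cfg.reject_threshold) & (area >= required)
    )
    out = np.where(s1, 1, np.where(keep2, 0, 2))
    return out


_DECISION_CODE = {
    Decision.KEEP: 0,
    Decision.DISCARD_STAGE1: 1,
    Decision.DISCARD_STAGE2: 2,
}


def clean_dataset(
    triplets: Iterable[tuple[str, str, QCTriplet]],
    cfg: CleanConfig = CleanConfig(),
) -> CleanReport:
    """Apply the cascade to (slice_id, group, triplet) records.

    The three output lists partition the input ids; discard counts are
    aggregated per patient group.
    """
    kept: list[str] = []
    d1: list[str] = []
    d2: list[str] = []
    per_group: dict[str, int] = {}
    for slice_id, group, t in triplets:
        decision = clean_slice(t, cfg)
        if decision is Decision.KEEP:
            kept.append(slice_id)
        else:
            (d1 if decision is Decision.DISCARD_STAGE1 else d2).append(slice_id)
            per_group[group] = per_group.get(group, 0) + 1
    return CleanReport(kept, d1, d2, per_group)


def readjust_tv(study, kept_slice_ids: Sequence[int] | Sequence[str]) -> float | None:
    """Recompute a patient's TV% over the surviving slices only.

    ``kept_slice_ids`` holds indices into ``study.slices`` (or slice ids of
    the form produced by the phantom cohort writer, resolved by position).
    Returns ``None`` when every slice was discarded (patient excluded).
    """
    kept = list(kept_slice_ids)
    if not kept:
        return None
    masks = [study.slices[int(i)][1] for i in kept]
    return patient_tv(masks)
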