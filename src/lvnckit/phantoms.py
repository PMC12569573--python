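"""Synthetic left-ventricle phantoms for short-axis slice analysis.

Real LVNC cohorts are hospital data and cannot ship with the package, so
every stage is exercised on procedurally generated phantoms that mimic the
morphology the pipeline cares about: a bright circular blood pool (inner
cavity), a compact myocardial ring around it (external layer), and a band of
trabecular blobs lining the cavity side of the wall.  Degenerate categories
reproduce the two discard classes of the quality-control stage: "no ring"
slices whose compact layer has an open arc, and "poor quality" slices with a
tiny cavity and bright artefacts.

Intensity model (before additive Gaussian noise): background 0.20, compact
layer 0.55, inner cavity 0.85, trabeculae 0.40.  The values are arbitrary
but fixed; they make the four classes separable by a small network while
leaving the compact-layer/trabeculae contrast the hardest, as in real MRI.

Patient series emulate a short-axis stack of about 7 slices whose ventricle
shrinks towards the extreme (apical/basal) slices.  Cohorts follow the
four-group composition of an LVNC study population: P (hypertrophic
cardiomyopathy, ~65 %), H (LVNC), X (mixed cardiomyopathies) and
T (titin-related cardiomyopathy).

All generation is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .cleaning import QCTriplet
from .geometry import NoForegroundError, bbox_from_mask
from .quantify import patient_tv

__all__ = [
    "PhantomSpec",
    "PatientStudy",
    "DEFAULT_GROUP_PROPORTIONS",
    "CLASS_INTENSITY",
    "generate_slice",
    "generate_patient",
    "generate_cohort",
    "simulate_qc_triplet",
]

Category = Literal["normal", "no_ring", "poor_quality"]
Group = Literal["P", "H", "X", "T"]

#: Mean image intensity per mask class (background, EL, IC, T).
CLASS_INTENSITY = np.array([0.20, 0.55, 0.85, 0.40])

#: Group mix of the emulated 450-patient study population (P, H, X, T).
DEFAULT_GROUP_PROPORTIONS = (293 / 450, 78 / 450, 69 / 450, 10 / 450)

#: Per-group range of the per-patient target trabecular fraction.
GROUP_TRABECULAR_RANGE = {
    "P": (0.15, 0.30),
    "H": (0.30, 0.45),
    "X": (0.10, 0.40),
    "T": (0.15, 0.35),
}


class InvalidSpecError(ValueError):
    """Raised when phantom geometry cannot fit the requested image."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, noise and category of one phantom slice."""

    image_size: int = 128
    cavity_radius: float = 32.0
    wall_thickness: float = 12.0
    trabecular_fraction: float = 0.25
    opening_angle: float = 0.0
    noise_sigma: float = 0.05
    artifact_count: int = 0
    category: Category = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.trabecular_fraction <= 1.0):
            raise InvalidSpecError("trabecular_fraction must lie in [0, 1]")
        if self.cavity_radius <= 0 or self.wall_thickness <= 0:
            raise InvalidSpecError("geometric fields must be positive")
        if self.image_size < 16:
            raise InvalidSpecError("image_size too small")
        if self.cavity_radius + self.wall_thickness >= self.image_size / 2.0:
            raise InvalidSpecError("ring does not fit inside the image")
        if (self.category == "no_ring") != (self.opening_angle > 0):
            raise InvalidSpecError(
                "category 'no_ring' if and only if opening_angle > 0"
            )
        if self.category == "poor_quality":
            if self.cavity_radius > 0.1 * self.image_size:
                raise InvalidSpecError("poor_quality requires a small cavity")
            if self.artifact_count < 1:
                raise InvalidSpecError("poor_quality requires artefacts")
        if not (0.0 <= self.opening_angle < 360.0):
            raise InvalidSpecError("opening_angle must lie in [0, 360)")


@dataclass
class PatientStudy:
    """Ordered short-axis stack of one patient with its ground-truth TV%."""

    patient_id: str
    group: Group
    slices: list[tuple[np.ndarray, np.ndarray]]
    tv_percent_truth: float
    slice_specs: list[PhantomSpec] = field(default_factory=list)


def _polar_grids(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    theta = np.degrees(np.arctan2(yy - c, xx - c)) % 360.0
    return r, theta


def generate_slice(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom slice.

    Returns ``(image, mask)``: a float image in [0, 1] and an aligned uint8
    label grid with values {0 background, 1 EL, 2 IC, 3 T}.  The trabecular
    pixel count is tuned so that area(T) / (area(T) + area(EL)) matches
    ``spec.trabecular_fraction`` to within one pixel.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    r, theta = _polar_grids(size)

    mask = np.zeros((size, size), dtype=np.uint8)
    mask[r <= spec.cavity_radius] = 2
    ring = (r > spec.cavity_radius) & (r <= spec.cavity_radius + spec.wall_thickness)
    if spec.opening_angle > 0:
        start = rng.uniform(0.0, 360.0)
        offset = (theta - start) % 360.0
        ring &= ~(offset < spec.opening_angle)
    mask[ring] = 1

    _paint_trabeculae(mask, r, spec, rng)

    image = CLASS_INTENSITY[mask].astype(float)
    for _ in range(spec.artifact_count):
        _paint_artifact(image, rng, size)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    return np.clip(image, 0.0, 1.0), mask


def _paint_trabeculae(
    mask: np.ndarray, r: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> None:
    f = spec.trabecular_fraction
    if f == 0.0:
        return
    n_el = int(np.count_nonzero(mask == 1))
    if f >= 1.0:
        raise InvalidSpecError("trabecular_fraction must be below 1 for a finite wall")
    target = int(round(f / (1.0 - f) * n_el))
    cavity = mask == 2
    n_cavity = int(cavity.sum())
    if target > 0.85 * n_cavity:
        raise InvalidSpecError("trabecular_fraction too high for this geometry")
    if target == 0:
        return

    size = spec.image_size
    c = (size - 1) / 2.0
    disk_r = max(2.0, 0.035 * size)
    yy, xx = np.mgrid[0:size, 0:size]
    painted = 0
    for _ in range(4000):
        if painted >= target:
            break
        phi = rng.uniform(0.0, 2.0 * math.pi)
        rad = spec.cavity_radius - 0.4 * disk_r
        dy, dx = c + rad * math.sin(phi), c + rad * math.cos(phi)
        rho = disk_r * rng.uniform(0.7, 1.3)
        blob = (np.hypot(yy - dy, xx - dx) <= rho) & (mask == 2)
        painted += int(np.count_nonzero(blob))
        mask[blob] = 3

    # Exactness: top up from the outermost cavity pixels (still adjacent to
    # the wall) or peel the innermost trabecular pixels back to cavity.
    if painted < target:
        cav_r = np.where(mask == 2, r, -np.inf).ravel()
        order = np.argsort(cav_r)[::-1][: target - painted]
        mask.ravel()[order] = 3
    elif painted > target:
        trab_r = np.where(mask == 3, r, np.inf).ravel()
        order = np.argsort(trab_r)[: painted - target]
        mask.ravel()[order] = 2


def _paint_artifact(image: np.ndarray, rng: np.random.Generator, size: int) -> None:
    """Bright streak or blob, intensity-only (not in the mask)."""
    if rng.random() < 0.5:  # streak
        row = int(rng.integers(0, size))
        width = int(rng.integers(1, max(2, size // 40) + 1))
        image[row : row + width, :] = 0.95
    else:  # blob
        cy, cx = rng.uniform(0, size, 2)
        rho = rng.uniform(0.02, 0.06) * size
        yy, xx = np.mgrid[0:size, 0:size]
        image[np.hypot(yy - cy, xx - cx) <= rho] = 0.95


def _slice_scale(i: int, n: int) -> float:
    """Ventricle size profile along the stack; extreme slices are smaller."""
    return 0.65 + 0.35 * math.sin(math.pi * (i + 0.5) / n)


def generate_patient(
    group: Group,
    n_slices: int = 7,
    spec_template: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    patient_id: str | None = None,
    no_ring_fraction: float = 0.0,
    poor_quality_fraction: float = 0.0,
) -> PatientStudy:
    """Generate one patient's short-axis stack.

    The template's cavity radius and wall thickness are scaled smoothly
    along the series; optional fractions of slices are replaced by the
    degenerate "no ring" / "poor quality" categories.  The ground-truth TV%
    is computed from the generated masks by summed-area quantification.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be at least 1")
    rng = np.random.default_rng(seed)
    slices: list[tuple[np.ndarray, np.ndarray]] = []
    specs: list[PhantomSpec] = []
    for i in range(n_slices):
        scale = _slice_scale(i, n_slices)
        spec = replace(
            spec_template,
            cavity_radius=spec_template.cavity_radius * scale,
            wall_thickness=max(2.0, spec_template.wall_thickness * scale),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        u = rng.random()
        if u < no_ring_fraction:
            spec = replace(
                spec,
                category="no_ring",
                opening_angle=float(rng.uniform(45.0, 120.0)),
            )
        elif u < no_ring_fraction + poor_quality_fraction:
            spec = replace(
                spec,
                category="poor_quality",
                cavity_radius=spec_template.image_size * float(rng.uniform(0.05, 0.1)),
                artifact_count=int(rng.integers(1, 5)),
            )
        img, msk = generate_slice(spec)
        slices.append((img, msk))
        specs.append(spec)
    tv = patient_tv([m for _, m in slices])
    return PatientStudy(
        patient_id=patient_id or f"{group}0000",
        group=group,
        slices=slices,
        tv_percent_truth=tv,
        slice_specs=specs,
    )


def _group_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n patients over the groups."""
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("group proportions must sum to 1")
    raw = [n * p for p in proportions]
    counts = [int(math.floor(x)) for x in raw]
    short = n - sum(counts)
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i]), reverse=True
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def generate_cohort(
    n_patients: int,
    group_proportions: Sequence[float] = DEFAULT_GROUP_PROPORTIONS,
    seed: int = 0,
    image_size: int = 128,
    no_ring_fraction: float = 0.0,
    poor_quality_fraction: float = 0.0,
) -> list[PatientStudy]:
    """Generate a cohort with the study's four-group composition.

    Group counts follow ``group_proportions`` by largest-remainder rounding;
    each patient gets 6-9 slices, a per-group trabecular-fraction draw and
    jittered ring geometry.  Patient ids are unique.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    counts = _group_counts(n_patients, group_proportions)
    rng = np.random.default_rng(seed)
    cohort: list[PatientStudy] = []
    for group, count in zip(("P", "H", "X", "T"), counts):
        lo, hi = GROUP_TRABECULAR_RANGE[group]
        for j in range(count):
            cavity_radius = image_size * float(rng.uniform(0.20, 0.27))
            # wall scaled to the cavity so the trabecular band always fits
            template = PhantomSpec(
                image_size=image_size,
                cavity_radius=cavity_radius,
                wall_thickness=cavity_radius * float(rng.uniform(0.28, 0.40)),
                trabecular_fraction=float(rng.uniform(lo, hi)),
                noise_sigma=0.05,
            )
            cohort.append(
                generate_patient(
                    group,
                    n_slices=int(rng.integers(6, 10)),
                    spec_template=template,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    patient_id=f"{group}{j:04d}",
                    no_ring_fraction=no_ring_fraction,
                    poor_quality_fraction=poor_quality_fraction,
                )
            )
    return cohort


def simulate_qc_triplet(
    slice_image: np.ndarray,
    mask: np.ndarray,
    spec: PhantomSpec,
    seed: int = 0,
) -> QCTriplet:
    """Emulate the two quality-control detectors on a phantom slice.

    Stands in for the trained open-ring and cavity-quality detectors: the
    open-ring confidence is high (>= 0.5) exactly when the compact layer has
    an opening; the cavity confidence grows with cavity size and ring
    completeness and drops with artefacts; the area is the cavity
    bounding-box area as a fraction of the image, plus bounded noise.
    """
    if slice_image.shape != mask.shape:
        raise ValueError("slice and mask must be aligned")
    rng = np.random.default_rng(seed)
    size = spec.image_size

    try:
        box = bbox_from_mask(mask, {2, 3})
        bbox_frac = box.area / float(size * size)
    except NoForegroundError:
        bbox_frac = 0.0

    ring_term = (1.0 - spec.opening_angle / 360.0) ** 2
    size_term = float(np.clip((bbox_frac - 0.03) / 0.05, 0.0, 1.0))
    conf_valid = float(
        np.clip(
            0.97 * ring_term
            - 0.35 * (1.0 - size_term)
            - 0.08 * spec.artifact_count
            + rng.uniform(-0.02, 0.02),
            0.0,
            1.0,
        )
    )
    if spec.opening_angle > 0:
        conf_open = float(
            np.clip(
                0.55
                + 0.35 * min(spec.opening_angle / 90.0, 1.0)
                + rng.uniform(-0.03, 0.03),
                0.5,
                1.0,
            )
        )
    else:
        conf_open = float(rng.uniform(0.0, 0.15))
    area = float(np.clip(bbox_frac + rng.uniform(-0.005, 0.005), 0.0, 1.0))
    return QCTriplet(conf_valid=conf_valid, conf_open=conf_open, area=area)
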