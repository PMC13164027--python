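"""Per-nucleus DAB-intensity statistic and four-class assignment.

Each segmented nucleus i gets an inverted mean DAB value

    mu_i = 1 - (1 / |Omega_i|) * sum over (x, y) in Omega_i of DAB(x, y)

computed on the normalized DAB map, so darker brown (stronger receptor
expression) means lower mu.  Three calibrated thresholds tau1 < tau2 < tau3
partition [0, 1] into Strong (mu < tau1), Moderate, Weak and Negative
(mu >= tau3).  Unstained, hematoxylin-only nuclei sit near mu = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError, ShapeError
from .scoring import CountTable
from .segmentation import InstanceMask
from .stains import DABMap, StainModel, deconvolve, normalize_dab

__all__ = [
    "StainClass",
    "ClassThresholds",
    "NucleusRecord",
    "CLASS_COLORS",
    "DEFAULT_THRESHOLDS",
    "mean_inverted_dab",
    "classify_mu",
    "classify_image",
    "render_class_overlay",
]


class StainClass(str, Enum):
    """Four staining-intensity categories, strongest first."""

    STRONG = "Strong"
    MODERATE = "Moderate"
    WEAK = "Weak"
    NEGATIVE = "Negative"

    @property
    def ordinal(self) -> int:
        """0 = Strong ... 3 = Negative; monotone in mu."""
        return list(StainClass).index(self)


#: Overlay colors: Negative blue, Weak green, Moderate yellow, Strong red.
CLASS_COLORS: dict[StainClass, tuple[int, int, int]] = {
    StainClass.STRONG: (255, 0, 0),
    StainClass.MODERATE: (255, 255, 0),
    StainClass.WEAK: (0, 255, 0),
    StainClass.NEGATIVE: (0, 0, 255),
}


@dataclass(frozen=True)
class ClassThresholds:
    """The three class boundaries (tau1, tau2, tau3) on the mu scale."""

    tau1: float = 0.89
    tau2: float = 0.94
    tau3: float = 0.975

    def __post_init__(self) -> None:
        if not (0.0 < self.tau1 < self.tau2 < self.tau3 < 1.0):
            raise ParameterError(
                f"thresholds must satisfy 0 < tau1 < tau2 < tau3 < 1, got "
                f"({self.tau1}, {self.tau2}, {self.tau3})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.tau1, self.tau2, self.tau3)


DEFAULT_THRESHOLDS = ClassThresholds()


@dataclass(frozen=True)
class NucleusRecord:
    """One nucleus: label id, pixel area, inverted mean DAB, class."""

    id: int
    area: int
    mu: float
    class_label: StainClass

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ParameterError("nucleus id must be >= 1")
        if self.area < 1:
            raise ParameterError("nucleus area must be >= 1")
        if not (0.0 <= self.mu <= 1.0):
            raise ParameterError(f"mu must lie in [0, 1], got {self.mu}")


def mean_inverted_dab(dab: DABMap, mask: InstanceMask) -> list[tuple[int, int, float]]:
    """Per-nucleus (id, area, mu) with mu = 1 - mean DAB over the nucleus.

    Sorted by label id; empty for an empty mask.
    """
    if dab.shape != mask.shape:
        raise ShapeError(f"DAB map shape {dab.shape} != mask shape {mask.shape}")
    ids = mask.ids
    if ids.size == 0:
        return []
    means = ndi.mean(dab.values, labels=mask.labels, index=ids)
    counts = np.bincount(mask.labels.ravel())
    return [
        (int(i), int(counts[i]), float(np.clip(1.0 - m, 0.0, 1.0)))
        for i, m in zip(ids, means)
    ]


def classify_mu(mu: float, thresholds: ClassThresholds = DEFAULT_THRESHOLDS) -> StainClass:
    """Map mu in [0, 1] to its staining class.

    Strong if mu < tau1; Moderate if tau1 <= mu < tau2; Weak if
    tau2 <= mu < tau3; Negative if mu >= tau3.  Boundaries belong to the
    weaker class.
    """
    if not (0.0 <= mu <= 1.0):
        raise ParameterError(f"mu must lie in [0, 1], got {mu}")
    if mu < thresholds.tau1:
        return StainClass.STRONG
    if mu < thresholds.tau2:
        return StainClass.MODERATE
    if mu < thresholds.tau3:
        return StainClass.WEAK
    return StainClass.NEGATIVE


def classify_image(
    rgb: np.ndarray,
    mask: InstanceMask,
    model: StainModel | None = None,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[NucleusRecord], CountTable]:
    """Full per-tile classification: unmix, normalize, average, threshold."""
    if model is None:
        model = StainModel()
    if rgb.shape[:2] != mask.shape:
        raise ShapeError(f"image shape {rgb.shape[:2]} != mask shape {mask.shape}")
    _, dab_od, _ = deconvolve(rgb, model)
    dab = normalize_dab(dab_od, model.od_reference)
    records = [
        NucleusRecord(id=i, area=a, mu=mu, class_label=classify_mu(mu, thresholds))
        for i, a, mu in mean_inverted_dab(dab, mask)
    ]
    tally = {c: 0 for c in StainClass}
    for rec in records:
        tally[rec.class_label] += 1
    counts = CountTable(
        strong=tally[StainClass.STRONG],
        moderate=tally[StainClass.MODERATE],
        weak=tally[StainClass.WEAK],
        negative=tally[StainClass.NEGATIVE],
    )
    return records, counts


def render_class_overlay(mask: InstanceMask, records: list[NucleusRecord]) -> np.ndarray:
    """Four-color class overlay: nucleus pixels colored by class, background black."""
    by_id = {rec.id: rec for rec in records}
    missing = [int(i) for i in mask.ids if int(i) not in by_id]
    if missing:
        raise ParameterError(f"mask labels without a record: {missing}")
    out = np.zeros((*mask.shape, 3), dtype=np.uint8)
    for rec in records:
        out[mask.labels == rec.id] = CLASS_COLORS[rec.class_label]
    return out
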