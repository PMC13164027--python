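"""Synthetic chromogenic-IHC tiles and count tables with known ground truth.

Tiles are built through the same Beer-Lambert forward model the unmixing
inverts: elliptical nuclei carry a constant hematoxylin od plus a
class-specific DAB od, the background carries a faint hematoxylin wash, and
the od maps are rendered to 8-bit RGB.  Constant-od ellipses keep the
per-nucleus mean DAB analytically predictable, so the generator can
guarantee — by recomputing mu through the actual unmixing path and
redrawing violators — that every nucleus lands strictly inside its intended
class band.  That makes a generated tile an end-to-end oracle for the whole
pipeline: segmentation, classification and scoring can all be checked
against construction-time truth without any external data.

The count-table generator draws per-image class counts from a three-part
mixture (all-negative ROIs, low-positive ROIs, strongly positive ROIs)
emulating the spread seen across real PR-IHC test slides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classification import (
    DEFAULT_THRESHOLDS,
    ClassThresholds,
    StainClass,
    classify_mu,
    mean_inverted_dab,
)
from .errors import CapacityError, ParameterError
from .scoring import CountTable
from .segmentation import InstanceMask
from .stains import StainModel, deconvolve, forward_mix, normalize_dab

__all__ = [
    "SyntheticSpec",
    "SyntheticTile",
    "generate_tile",
    "CountMixture",
    "generate_count_table",
    "reference_score_fixture",
]

# DAB od sampling bands per class, chosen so the resulting mu
# (1 - mean normalized DAB) sits strictly inside its class band under the
# default thresholds (0.89, 0.94, 0.975) with margin for 8-bit quantization.
_DEFAULT_CLASS_DAB_OD: tuple[tuple[float, float], ...] = (
    (0.20, 0.50),    # Strong   -> mu ~ 0.50-0.80
    (0.075, 0.092),  # Moderate -> mu ~ 0.908-0.925
    (0.037, 0.052),  # Weak     -> mu ~ 0.948-0.963
    (0.000, 0.012),  # Negative -> mu ~ 0.988-1.0
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic tile.

    ``n_per_class`` orders counts as (Strong, Moderate, Weak, Negative).
    ``overlap_fraction`` is the maximum tolerated overlap between a new
    ellipse and already-placed nuclei, as a fraction of the new ellipse's
    area; 0 demands disjoint nuclei with a small spacing margin.
    """

    height: int = 256
    width: int = 256
    n_per_class: tuple[int, int, int, int] = (5, 5, 5, 5)
    radius_range: tuple[int, int] = (6, 12)
    overlap_fraction: float = 0.0
    class_dab_od: tuple[tuple[float, float], ...] = _DEFAULT_CLASS_DAB_OD
    hematoxylin_od: tuple[float, float] = (0.45, 0.70)
    background_hematoxylin_od: float = 0.02
    background_dab_od: float = 0.0
    texture_od_sd: float = 0.0
    spacing: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] < 3:
            raise ParameterError("minimum radius must be >= 3 px")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ParameterError("overlap_fraction must lie in [0, 1)")
        if len(self.n_per_class) != 4 or any(n < 0 for n in self.n_per_class):
            raise ParameterError("n_per_class must be four non-negative counts")
        if len(self.class_dab_od) != 4:
            raise ParameterError("class_dab_od must give four (lo, hi) bands")


@dataclass(frozen=True)
class SyntheticTile:
    """A rendered tile with its construction-time ground truth."""

    rgb: np.ndarray
    mask: InstanceMask
    classes: tuple[StainClass, ...] = field(default=())  # per nucleus id 1..N
    mu: tuple[float, ...] = field(default=())

    @property
    def counts(self) -> CountTable:
        tally = {c: 0 for c in StainClass}
        for cls in self.classes:
            tally[cls] += 1
        return CountTable(
            strong=tally[StainClass.STRONG],
            moderate=tally[StainClass.MODERATE],
            weak=tally[StainClass.WEAK],
            negative=tally[StainClass.NEGATIVE],
        )


def _ellipse_pixels(
    center: tuple[float, float], axes: tuple[float, float], theta: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    cy, cx = center
    a, b = axes
    r_max = int(np.ceil(max(a, b))) + 1
    y0, y1 = max(0, int(cy) - r_max), min(shape[0], int(cy) + r_max + 1)
    x0, x1 = max(0, int(cx) - r_max), min(shape[1], int(cx) + r_max + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return yy[inside], xx[inside]


def generate_tile(
    spec: SyntheticSpec,
    model: StainModel | None = None,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
    max_place_attempts: int = 10_000,
    max_redraws: int = 100,
) -> SyntheticTile:
    """Render a tile whose nuclei provably classify into their target classes.

    Ellipses are placed by rejection sampling honoring
    ``spec.overlap_fraction``; DAB od values are drawn per class and
    verified by running the rendered image back through unmixing — any
    nucleus whose recovered mu falls outside its class band is redrawn
    (up to ``max_redraws`` rounds).  Fully reproducible from ``spec.seed``.
    """
    if model is None:
        model = StainModel()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    # --- placement -------------------------------------------------------
    target_classes: list[StainClass] = []
    for cls, n in zip(StainClass, spec.n_per_class):
        target_classes.extend([cls] * n)
    order = rng.permutation(len(target_classes))
    target_classes = [target_classes[i] for i in order]

    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)  # nuclei plus spacing margin
    pixel_lists: list[tuple[np.ndarray, np.ndarray]] = []
    attempts = 0
    for lab_id in range(1, len(target_classes) + 1):
        placed = False
        while not placed:
            attempts += 1
            if attempts > max_place_attempts:
                raise CapacityError(
                    f"could not place nucleus {lab_id} within {max_place_attempts} "
                    "attempts; use a larger tile or fewer/smaller nuclei"
                )
            a = rng.uniform(spec.radius_range[0], spec.radius_range[1])
            b = rng.uniform(spec.radius_range[0], min(a, spec.radius_range[1]))
            theta = rng.uniform(0, np.pi)
            margin = max(a, b) + spec.spacing
            cy = rng.uniform(margin, spec.height - margin)
            cx = rng.uniform(margin, spec.width - margin)
            ys, xs = _ellipse_pixels((cy, cx), (a, b), theta, shape)
            if ys.size < 20:
                continue
            overlap = np.count_nonzero(occupied[ys, xs])
            if spec.overlap_fraction == 0.0:
                if overlap > 0:
                    continue
            elif overlap > spec.overlap_fraction * ys.size:
                continue
            labels[ys, xs] = lab_id
            pixel_lists.append((ys, xs))
            gy, gx = _ellipse_pixels(
                (cy, cx), (a + spec.spacing, b + spec.spacing), theta, shape
            )
            occupied[gy, gx] = True
            placed = True

    mask = InstanceMask(labels=labels)

    # --- staining --------------------------------------------------------
    n = len(target_classes)
    hem_per_nucleus = rng.uniform(*spec.hematoxylin_od, size=n)
    dab_per_nucleus = np.array(
        [rng.uniform(*spec.class_dab_od[cls.ordinal]) for cls in target_classes]
    )

    def render(dab_vals: np.ndarray) -> np.ndarray:
        hem = np.full(shape, spec.background_hematoxylin_od)
        dab = np.full(shape, spec.background_dab_od)
        if spec.texture_od_sd > 0:
            hem = hem + rng.normal(0, spec.texture_od_sd, shape)
        for idx, (ys, xs) in enumerate(pixel_lists):
            hem[ys, xs] = hem_per_nucleus[idx]
            dab[ys, xs] = dab_vals[idx]
        return forward_mix(np.clip(hem, 0, None), np.clip(dab, 0, None), model)

    def band(cls: StainClass) -> tuple[float, float]:
        taus = (0.0, *thresholds.as_tuple(), 1.0 + 1e-12)
        o = cls.ordinal  # Strong=0 ... Negative=3
        return taus[o], taus[o + 1]  # [lo, hi): Strong [0, tau1), ...

    rgb = render(dab_per_nucleus)
    mus: np.ndarray = np.empty(n)
    for _ in range(max_redraws):
        _, dab_od, _ = deconvolve(rgb, model)
        dab_map = normalize_dab(dab_od, model.od_reference)
        stats = mean_inverted_dab(dab_map, mask)
        mus = np.array([mu for _, _, mu in stats])
        bad = [
            i
            for i, cls in enumerate(target_classes)
            if not (band(cls)[0] <= mus[i] < band(cls)[1])
        ]
        # Negative nuclei may sit exactly at mu = 1.0 (clip), still in band
        bad = [
            i
            for i in bad
            if not (target_classes[i] is StainClass.NEGATIVE and mus[i] >= thresholds.tau3)
        ]
        if not bad:
            break
        for i in bad:
            lo, hi = spec.class_dab_od[target_classes[i].ordinal]
            dab_per_nucleus[i] = rng.uniform(lo, hi)
        rgb = render(dab_per_nucleus)
    else:
        raise CapacityError(
            "could not realise the requested class bands after redraws; "
            "widen class_dab_od or lower texture_od_sd"
        )

    for i, cls in enumerate(target_classes):
        assert classify_mu(float(mus[i]), thresholds) is cls

    return SyntheticTile(
        rgb=rgb, mask=mask, classes=tuple(target_classes), mu=tuple(float(m) for m in mus)
    )


@dataclass(frozen=True)
class CountMixture:
    """Mixture over ROI archetypes for the count-table generator.

    Weights order: (all-negative, low-positive, strongly-positive); they
    need not sum to 1 (normalised internally).  Totals are drawn uniformly
    from ``total_range``; the defaults emulate the spread of nucleus counts
    and positivity seen across representative PR-IHC test ROIs (roughly one
    fifth all-negative, a modest low-positive tail, and a strongly positive
    majority).
    """

    weights: tuple[float, float, float] = (0.18, 0.16, 0.66)
    total_range: tuple[int, int] = (40, 280)
    low_positive_max_fraction: float = 0.2

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights) or sum(self.weights) <= 0:
            raise ParameterError("mixture weights must be non-negative, not all zero")


def generate_count_table(
    n_images: int, mixture: CountMixture | None = None, seed: int = 0
) -> list[CountTable]:
    """Draw per-image class counts from the ROI-archetype mixture."""
    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    if mixture is None:
        mixture = CountMixture()
    rng = np.random.default_rng(seed)
    w = np.asarray(mixture.weights, dtype=float)
    w = w / w.sum()
    tables: list[CountTable] = []
    for _ in range(n_images):
        total = int(rng.integers(mixture.total_range[0], mixture.total_range[1] + 1))
        comp = rng.choice(3, p=w)
        if comp == 0:  # all-negative ROI
            counts = (0, 0, 0, total)
        elif comp == 1:  # low-positive ROI: a few weak/moderate nuclei
            pos = int(rng.integers(1, max(2, int(mixture.low_positive_max_fraction * total))))
            weak = int(rng.integers(0, pos + 1))
            moderate = pos - weak
            counts = (0, moderate, weak, total - pos)
        else:  # strongly positive ROI
            pos_frac = rng.uniform(0.4, 0.98)
            pos = max(1, int(round(pos_frac * total)))
            p = rng.dirichlet((6.0, 2.0, 1.5))
            strong = int(round(p[0] * pos))
            moderate = int(round(p[1] * pos))
            strong = min(strong, pos)
            moderate = min(moderate, pos - strong)
            weak = pos - strong - moderate
            counts = (strong, moderate, weak, total - pos)
        tables.append(CountTable(*counts))
    return tables


# 50 reference ROIs: (strong, moderate, weak, negative) -> (P, I, total).
_REFERENCE_ROWS: tuple[tuple[tuple[int, int, int, int], tuple[int, int, int]], ...] = (
    ((176, 51, 33, 19), (5, 3, 8)),
    ((33, 41, 51, 92), (4, 1, 5)),
    ((0, 0, 0, 148), (0, 0, 0)),
    ((0, 0, 0, 115), (0, 0, 0)),
    ((42, 38, 33, 22), (5, 3, 8)),
    ((69, 33, 13, 17), (5, 3, 8)),
    ((4, 16, 16, 80), (3, 2, 5)),
    ((19, 14, 19, 71), (4, 3, 7)),
    ((0, 0, 0, 123), (0, 0, 0)),
    ((32, 8, 6, 173), (3, 3, 6)),
    ((23, 15, 14, 110), (3, 3, 6)),
    ((42, 6, 7, 27), (5, 3, 8)),
    ((0, 0, 1, 55), (2, 1, 3)),
    ((82, 50, 59, 54), (5, 3, 8)),
    ((31, 55, 76, 81), (5, 1, 6)),
    ((0, 0, 19, 20), (4, 1, 5)),
    ((53, 18, 24, 39), (5, 3, 8)),
    ((31, 26, 56, 42), (5, 1, 6)),
    ((20, 21, 34, 39), (4, 1, 5)),
    ((233, 36, 4, 6), (5, 3, 8)),
    ((42, 11, 25, 51), (4, 3, 7)),
    ((30, 12, 18, 79), (4, 3, 7)),
    ((0, 0, 23, 121), (3, 1, 4)),
    ((73, 16, 1, 10), (5, 3, 8)),
    ((1, 1, 2, 115), (2, 1, 3)),
    ((0, 0, 2, 65), (2, 1, 3)),
    ((35, 65, 38, 38), (5, 2, 7)),
    ((0, 0, 0, 84), (0, 0, 0)),
    ((78, 22, 3, 111), (4, 3, 7)),
    ((0, 0, 1, 39), (2, 1, 3)),
    ((3, 0, 18, 92), (3, 1, 4)),
    ((7, 15, 39, 71), (4, 1, 5)),
    ((64, 6, 1, 21), (5, 3, 8)),
    ((47, 26, 20, 38), (5, 3, 8)),
    ((0, 0, 0, 97), (0, 0, 0)),
    ((107, 5, 5, 13), (5, 3, 8)),
    ((98, 5, 0, 3), (5, 3, 8)),
    ((133, 43, 31, 5), (5, 3, 8)),
    ((22, 18, 20, 24), (5, 3, 8)),
    ((0, 0, 0, 160), (0, 0, 0)),
    ((148, 27, 6, 15), (5, 3, 8)),
    ((136, 37, 6, 10), (5, 3, 8)),
    ((0, 0, 0, 88), (0, 0, 0)),
    ((0, 0, 0, 47), (0, 0, 0)),
    ((0, 0, 0, 138), (0, 0, 0)),
    ((92, 77, 31, 7), (5, 3, 8)),
    ((126, 17, 6, 6), (5, 3, 8)),
    ((35, 18, 14, 11), (5, 3, 8)),
    ((75, 1, 1, 9), (5, 3, 8)),
    ((88, 14, 11, 58), (5, 3, 8)),
)


def reference_score_fixture() -> list[tuple[CountTable, tuple[int, int, int]]]:
    """50 reference PR-IHC test-ROI count rows with their (P, I, total) scores.

    Covers the clinically interesting corners: intensity ties, percentages
    between the integer bin edges, sub-2% low-positive ROIs, and nine
    all-negative ROIs.  Serves as the exact oracle for the scoring rules.
    """
    return [(CountTable(*counts), expected) for counts, expected in _REFERENCE_ROWS]
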