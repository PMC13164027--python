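"""Automatic threshold calibration by exhaustive grid search.

Given a calibration table of per-nucleus mu values paired with expert class
labels, the three class boundaries are chosen by enumerating every monotone
triple tau1 < tau2 < tau3 on a regular grid (default [0.5, 1.0] in steps of
0.005, ~1.7e5 triples) and keeping the triple that maximizes the chosen
objective (macro-F1 by default, accuracy also available).  The search is
exact, deterministic, and order-invariant: per-class cumulative counts of
mu below each grid point turn one candidate triple into a 4x4 confusion
matrix in O(1), and all triples are evaluated vectorized.  Ties on the
objective resolve to the lexicographically smallest triple.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .classification import ClassThresholds, StainClass
from .errors import CalibrationError, ParameterError

__all__ = ["CalibrationSet", "calibrate_thresholds"]

_CLASS_ORDER = list(StainClass)  # Strong, Moderate, Weak, Negative


@dataclass(frozen=True)
class CalibrationSet:
    """Per-nucleus (mu, ground-truth class) pairs used to fit thresholds."""

    pairs: tuple[tuple[float, StainClass], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise CalibrationError("calibration set is empty")
        pairs = tuple(
            (float(mu), StainClass(cls)) for mu, cls in self.pairs
        )
        for mu, _ in pairs:
            if not (0.0 <= mu <= 1.0):
                raise ParameterError(f"calibration mu must lie in [0, 1], got {mu}")
        object.__setattr__(self, "pairs", pairs)

    @property
    def n_classes(self) -> int:
        return len({cls for _, cls in self.pairs})

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        mus = np.array([mu for mu, _ in self.pairs])
        gt = np.array([_CLASS_ORDER.index(cls) for _, cls in self.pairs])
        return mus, gt


def _macro_f1_from_bins(tp: np.ndarray, pred_tot: np.ndarray, gt_tot: np.ndarray) -> np.ndarray:
    # one-vs-rest F1 = 2*TP / (pred_total + gt_total); absent classes -> 0
    denom = pred_tot + gt_tot[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * tp / denom, 0.0)
    return f1.mean(axis=1)


def calibrate_thresholds(
    cal: CalibrationSet,
    grid_lo: float = 0.5,
    grid_hi: float = 1.0,
    step: float = 0.005,
    objective: str | Callable[[np.ndarray], float] = "macro_f1",
) -> tuple[ClassThresholds, float]:
    """Grid-search the (tau1, tau2, tau3) maximizing the objective on ``cal``.

    Parameters
    ----------
    cal
        Calibration pairs; must contain at least two distinct classes.
    grid_lo, grid_hi, step
        Regular threshold grid.  The defaults put the conventional
        (0.89, 0.94, 0.975) triple exactly on the grid.
    objective
        ``"macro_f1"``, ``"accuracy"``, or a callable taking a 4x4 confusion
        matrix (rows = ground truth, class order Strong, Moderate, Weak,
        Negative) and returning a score to maximize.

    Returns
    -------
    (thresholds, achieved) — the lexicographically smallest maximizing
    triple and the objective value it achieves.
    """
    if not grid_lo < grid_hi:
        raise ParameterError("grid_lo must be < grid_hi")
    if step <= 0:
        raise ParameterError("step must be > 0")
    if cal.n_classes < 2:
        raise CalibrationError(
            "calibration needs at least 2 distinct ground-truth classes; "
            "the objective is degenerate on a single class"
        )

    n_steps = int(round((grid_hi - grid_lo) / step))
    # round away accumulated float drift so grid points like 0.93 are exact
    grid = np.round(grid_lo + step * np.arange(n_steps + 1), 10)
    # thresholds must lie strictly inside (0, 1) to be valid boundaries
    grid = grid[(grid > 0.0) & (grid < 1.0)]
    if grid.size < 3:
        raise ParameterError("grid must contain at least 3 points inside (0, 1)")
    mus, gt = cal.arrays()
    n_total = mus.size

    # cum[c, g] = number of class-c nuclei with mu < grid[g]
    cum = np.empty((4, grid.size), dtype=np.int64)
    gt_tot = np.empty(4, dtype=np.int64)
    for c in range(4):
        mc = np.sort(mus[gt == c])
        gt_tot[c] = mc.size
        cum[c] = np.searchsorted(mc, grid, side="left")

    triples = np.array(list(combinations(range(grid.size), 3)), dtype=np.int64)
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]

    # predicted-bin composition per gt class, shape (n_triples, 4 gt classes)
    strong_bin = cum[:, i].T
    moderate_bin = (cum[:, j] - cum[:, i]).T
    weak_bin = (cum[:, k] - cum[:, j]).T
    negative_bin = (gt_tot[:, None] - cum[:, k]).T
    bins = np.stack([strong_bin, moderate_bin, weak_bin, negative_bin], axis=1)
    # bins[t, p, c] = count of gt class c predicted as p for triple t

    if callable(objective):
        scores = np.array([float(objective(bins[t].T)) for t in range(len(triples))])
    elif objective == "macro_f1":
        tp = bins[:, np.arange(4), np.arange(4)]
        pred_tot = bins.sum(axis=2)
        scores = _macro_f1_from_bins(tp, pred_tot, gt_tot)
    elif objective == "accuracy":
        tp = bins[:, np.arange(4), np.arange(4)]
        scores = tp.sum(axis=1) / n_total
    else:
        raise ParameterError(f"unknown objective {objective!r}")

    best = int(np.argmax(scores))  # first occurrence = lexicographically smallest
    t1, t2, t3 = grid[triples[best]]
    return ClassThresholds(tau1=float(t1), tau2=float(t2), tau3=float(t3)), float(scores[best])


def calibration_set_from_lists(
    mus: Sequence[float], classes: Sequence[str | StainClass]
) -> CalibrationSet:
    """Build a :class:`CalibrationSet` from parallel mu / class sequences."""
    if len(mus) != len(classes):
        raise ParameterError("mu and class sequences must have equal length")
    return CalibrationSet(pairs=tuple((m, StainClass(c)) for m, c in zip(mus, classes)))
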