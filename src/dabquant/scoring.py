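"""Allred scoring: proportion score P, intensity score I, total P + I.

The Allred system summarises hormone-receptor IHC on a 0-8 scale:

* P (0-5) bins the percentage of positive nuclei: 0 -> 0; (0, 1)% -> 1;
  [1, 10]% -> 2; (10, 33]% -> 3; (33, 66]% -> 4; > 66% -> 5.  The
  right-closed real-valued bins extend the clinical integer table so that
  every percentage is assigned.
* I (0-3) is the dominant (modal) intensity among positive nuclei:
  Weak 1, Moderate 2, Strong 3; ties go to the stronger class; 0 when no
  nucleus is positive.
* total = P + I, so totals are 0 or 2-8 (1 is unreachable).  Totals 0 and 2
  read out as receptor-negative (endocrine therapy not indicated), 3-8 as
  positive.

An image with zero nuclei raises rather than scoring 0: an empty ROI is not
evidence of a negative tumour.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError, UndefinedScoreError

__all__ = [
    "CountTable",
    "AllredResult",
    "positive_percentage",
    "proportion_score",
    "intensity_score",
    "allred",
    "score_counts_frame",
]


@dataclass(frozen=True)
class CountTable:
    """Nucleus counts per staining class for one image/ROI."""

    strong: int = 0
    moderate: int = 0
    weak: int = 0
    negative: int = 0

    def __post_init__(self) -> None:
        for name in ("strong", "moderate", "weak", "negative"):
            v = getattr(self, name)
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise ParameterError(f"count '{name}' must be an integer, got {v!r}") from None
            if isinstance(v, bool) or iv != v or iv < 0:
                raise ParameterError(f"count '{name}' must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, iv)

    @property
    def positive(self) -> int:
        return self.strong + self.moderate + self.weak

    @property
    def total(self) -> int:
        return self.positive + self.negative


@dataclass(frozen=True)
class AllredResult:
    """Scores for one image: % positive, P, I, total, clinical read-out."""

    positive_pct: float
    P: int
    I: int
    total: int
    recommendation: str  # "negative" (0, 2) or "positive" (3-8)


def positive_percentage(counts: CountTable) -> float:
    """Percent positive nuclei, 100 * (strong+moderate+weak) / total."""
    if counts.total == 0:
        raise UndefinedScoreError("no nuclei: positive percentage is undefined")
    return 100.0 * counts.positive / counts.total


def proportion_score(positive_pct: float) -> int:
    """Allred proportion score P (0-5) from the percent-positive value."""
    if not (0.0 <= positive_pct <= 100.0):
        raise ParameterError(f"percentage must lie in [0, 100], got {positive_pct}")
    if positive_pct == 0:
        return 0
    if positive_pct < 1:
        return 1
    if positive_pct <= 10:
        return 2
    if positive_pct <= 33:
        return 3
    if positive_pct <= 66:
        return 4
    return 5


def intensity_score(counts: CountTable) -> int:
    """Allred intensity score I (0-3): modal positive class, ties to stronger."""
    if counts.positive == 0:
        return 0
    if counts.strong >= counts.moderate and counts.strong >= counts.weak:
        return 3
    if counts.moderate >= counts.weak:
        return 2
    return 1


def allred(counts: CountTable) -> AllredResult:
    """Full Allred read-out for one image's class counts."""
    pct = positive_percentage(counts)
    p = proportion_score(pct)
    i = intensity_score(counts)
    total = p + i
    return AllredResult(
        positive_pct=pct,
        P=p,
        I=i,
        total=total,
        recommendation="negative" if total in (0, 2) else "positive",
    )


def score_counts_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Score a table of per-image counts (columns strong/moderate/weak/negative).

    Returns a copy with positive_pct (2 decimals), P, I, allred and
    recommendation columns appended; other columns pass through.
    """
    required = {"strong", "moderate", "weak", "negative"}
    missing = required - set(frame.columns)
    if missing:
        raise ParameterError(f"counts table missing columns: {sorted(missing)}")
    out = frame.copy()
    results = [
        allred(
            CountTable(
                strong=int(r.strong),
                moderate=int(r.moderate),
                weak=int(r.weak),
                negative=int(r.negative),
            )
        )
        for r in frame.itertuples()
    ]
    out["positive_pct"] = [round(r.positive_pct, 2) for r in results]
    out["P"] = [r.P for r in results]
    out["I"] = [r.I for r in results]
    out["allred"] = [r.total for r in results]
    out["recommendation"] = [r.recommendation for r in results]
    return out
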