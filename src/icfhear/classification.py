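"""Hearing-loss classification from audiometry and disability degrees from scores.

PTA classes follow the Global Burden of Disease expert-group bands with
half-open intervals: <20 normal, [20,35) mild, [35,50) moderate,
[50,65) moderately severe; >=65 is outside the validated range.

Disability degrees partition the 0-10 score scale at M-SD, M and M+SD,
where M/SD come either from the published population values or are
derived from a supplied score distribution.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "HearingCategory",
    "DisabilityDegree",
    "DisabilityThresholds",
    "PAPER_THRESHOLDS",
    "pta",
    "classify_hearing",
    "derive_thresholds",
    "classify_disability",
    "concordance_table",
]

PTA_FREQUENCIES_KHZ = (0.5, 1.0, 2.0, 4.0)


class HearingCategory(Enum):
    NORMAL = "normal"
    MILD = "mild"
    MODERATE = "moderate"
    MODERATELY_SEVERE = "moderately_severe"
    OUT_OF_VALIDATED_RANGE = "out_of_validated_range"


class DisabilityDegree(Enum):
    NO = "no"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass(frozen=True)
class DisabilityThresholds:
    """Population mean/SD defining the degree cut points on a 0-10 score."""

    score_type: str  # hearing_related | non_hearing_related | speech_perception
    mean: float
    sd: float
    source: str = "COHORT_DERIVED"  # or PAPER_TABLE6

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("sd must be strictly positive (degenerate score distribution)")

    @property
    def cuts(self) -> tuple[float, float, float]:
        """(M - SD, M, M + SD)."""
        return (self.mean - self.sd, self.mean, self.mean + self.sd)


#: published population thresholds (score-scale mean and SD implied by the
#: printed cut points: speech 2.4/1.7, hearing 2.5/1.8, non-hearing 1.8/1.3)
PAPER_THRESHOLDS = {
    "speech_perception": DisabilityThresholds("speech_perception", 2.4, 1.7, "PAPER_TABLE6"),
    "hearing_related": DisabilityThresholds("hearing_related", 2.5, 1.8, "PAPER_TABLE6"),
    "non_hearing_related": DisabilityThresholds("non_hearing_related", 1.8, 1.3, "PAPER_TABLE6"),
}


def pta(thresholds) -> float:
    """Better-ear pure-tone average across 0.5/1/2/4 kHz.

    ``thresholds`` is a pair of 4-tuples of dB HL values (one per ear).
    Returns the smaller of the two per-ear means.  No imputation: any
    missing or non-finite threshold is an error.
    """
    try:
        left, right = thresholds
    except (TypeError, ValueError):
        raise ValueError("expected thresholds for exactly two ears") from None
    means = []
    for ear, vals in (("first", left), ("second", right)):
        vals = tuple(vals)
        if len(vals) != len(PTA_FREQUENCIES_KHZ):
            raise ValueError(
                f"{ear} ear: expected {len(PTA_FREQUENCIES_KHZ)} thresholds "
                f"(at {PTA_FREQUENCIES_KHZ} kHz), got {len(vals)}"
            )
        if not all(isinstance(v, (int, float)) and math.isfinite(v) for v in vals):
            raise ValueError(f"{ear} ear: non-finite or missing threshold in {vals}")
        means.append(sum(vals) / len(vals))
    return min(means)


def classify_hearing(pta_value: float) -> HearingCategory:
    """Classify a better-ear PTA (dB HL) into a hearing-loss category."""
    if not math.isfinite(pta_value):
        raise ValueError("PTA must be finite")
    if pta_value < 20:
        return HearingCategory.NORMAL
    if pta_value < 35:
        return HearingCategory.MILD
    if pta_value < 50:
        return HearingCategory.MODERATE
    if pta_value < 65:
        return HearingCategory.MODERATELY_SEVERE
    return HearingCategory.OUT_OF_VALIDATED_RANGE


def derive_thresholds(scores: Iterable[float], score_type: str) -> DisabilityThresholds:
    """Thresholds from a score distribution: mean and sample (n-1) SD."""
    vals = [float(s) for s in scores]
    if len(vals) < 2:
        raise ValueError("need at least 2 scores to derive thresholds")
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("scores must be finite")
    m = statistics.fmean(vals)
    sd = statistics.stdev(vals)
    if sd == 0:
        raise ValueError("zero score variance: thresholds degenerate")
    return DisabilityThresholds(score_type=score_type, mean=m, sd=sd, source="COHORT_DERIVED")


def classify_disability(score: float, thresholds: DisabilityThresholds) -> DisabilityDegree:
    """Degree of a normalized 0-10 score under M/SD cut points.

    Intervals are half-open on the right: [0, M-SD) no, [M-SD, M) mild,
    [M, M+SD) moderate, [M+SD, ...] severe.
    """
    if not 0 <= score <= 10:
        raise ValueError(f"score must be within [0, 10], got {score}")
    lo, mid, hi = thresholds.cuts
    if score < lo:
        return DisabilityDegree.NO
    if score < mid:
        return DisabilityDegree.MILD
    if score < hi:
        return DisabilityDegree.MODERATE
    return DisabilityDegree.SEVERE


# fixed display orders for the cross-tabulation
_PTA_ORDER = [c.value for c in HearingCategory]
_DEGREE_ORDER = [d.value for d in DisabilityDegree]


def concordance_table(
    pta_values: Sequence[float],
    scores: Sequence[float],
    thresholds: DisabilityThresholds,
) -> dict:
    """Cross-tabulate PTA-based hearing category against score-based degree.

    Returns ``{"counts": {pta_cat: {degree: n}}, "n": N, "marginals": ...}``
    including the ratio of "no disability by score" to "normal hearing by
    PTA" counts (NaN when the PTA margin is empty).
    """
    if len(pta_values) != len(scores):
        raise ValueError("pta_values and scores must be aligned")
    if len(scores) == 0:
        raise ValueError("empty overlap: nothing to cross-tabulate")
    counts = {c: {d: 0 for d in _DEGREE_ORDER} for c in _PTA_ORDER}
    for p, s in zip(pta_values, scores):
        counts[classify_hearing(p).value][classify_disability(s, thresholds).value] += 1
    pta_marg = {c: sum(row.values()) for c, row in counts.items()}
    deg_marg = {d: sum(counts[c][d] for c in _PTA_ORDER) for d in _DEGREE_ORDER}
    no_by_pta = pta_marg["normal"]
    ratio = deg_marg["no"] / no_by_pta if no_by_pta else math.nan
    return {
        "counts": counts,
        "n": len(scores),
        "pta_marginals": pta_marg,
        "degree_marginals": deg_marg,
        "no_by_score_over_no_by_pta": ratio,
    }
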