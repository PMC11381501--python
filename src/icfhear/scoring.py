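"""Outcome scores: hearing-related, non-hearing-related, speech perception.

Grades on facilitator items H.75-H.80 are mirrored (4 - g) before
aggregation so that 4 always means maximal hardship.  Raw group sums are
normalized onto a 0-10 scale.  Three normalization modes exist:

* ``PUBLISHED`` — the printed coefficients 0.067 / 0.061 / 0.0782.  Note
  0.067 is a truncation of 10/148 = 0.06756..., kept verbatim for
  reproducibility of reported values.
* ``EXACT`` — 10 / (4 * group size).
* ``PRORATED`` — 10 * raw / (4 * n_graded); tolerates non-gradable items
  and equals EXACT at full coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .item_bank import Item, ItemBank, items_in_group
from .responses import Respondent, ResponseValue

__all__ = [
    "ScoringMode",
    "ScoringPolicy",
    "GroupScore",
    "ScoreSet",
    "NONGRADABLE",
    "mirror_value",
    "coded_value",
    "normalization_coefficient",
    "score_respondent",
    "PUBLISHED_COEFFICIENTS",
]


class ScoringMode(Enum):
    PUBLISHED = "published"
    EXACT = "exact"
    PRORATED = "prorated"


#: printed per-raw-point weights, keyed by group size
PUBLISHED_COEFFICIENTS = {37: 0.067, 41: 0.061, 32: 0.0782}

_GROUPS = ("hearing_related", "non_hearing_related", "speech_perception")


class _NonGradable:
    __slots__ = ()

    def __repr__(self):
        return "NONGRADABLE"


NONGRADABLE = _NonGradable()


@dataclass(frozen=True)
class ScoringPolicy:
    mode: ScoringMode = ScoringMode.PRORATED
    min_coverage: float = 0.80


@dataclass(frozen=True)
class GroupScore:
    raw: float
    norm: float | None
    coverage: float
    n_items: int
    n_graded: int
    valid: bool


@dataclass(frozen=True)
class ScoreSet:
    respondent_id: str
    mode: ScoringMode
    hearing_related: GroupScore
    non_hearing_related: GroupScore
    speech_perception: GroupScore

    def group(self, name: str) -> GroupScore:
        return getattr(self, name)


def mirror_value(grade: int) -> int:
    """Mirror a facilitator grade: 4 -> 0, 3 -> 1, 2 -> 2, 1 -> 3, 0 -> 4."""
    if grade not in (0, 1, 2, 3, 4):
        raise ValueError(f"grade must be 0..4, got {grade!r}")
    return 4 - grade


def coded_value(item: Item, value: ResponseValue):
    """Hardship-aligned numeric value of a response, or NONGRADABLE.

    Mirroring applies only to items with MIRRORED polarity, so a coded 4
    always corresponds to the highest level of hardship.
    """
    if not value.gradable:
        return NONGRADABLE
    if item.polarity == "MIRRORED":
        return mirror_value(value.grade)
    return value.grade


def normalization_coefficient(group_size: int, mode: ScoringMode = ScoringMode.EXACT) -> float:
    """Weight per raw point mapping a full-coverage raw score onto 0-10."""
    if mode is ScoringMode.PUBLISHED:
        try:
            return PUBLISHED_COEFFICIENTS[group_size]
        except KeyError:
            raise ValueError(
                f"no published coefficient for group size {group_size}; "
                f"known sizes: {sorted(PUBLISHED_COEFFICIENTS)}"
            ) from None
    if group_size <= 0:
        raise ValueError("group size must be positive")
    return 10.0 / (4 * group_size)


def _score_group(respondent: Respondent, bank: ItemBank, group: str,
                 policy: ScoringPolicy) -> GroupScore:
    ids = items_in_group(bank, group)
    raw = 0
    n_graded = 0
    for item_id in ids:
        v = coded_value(bank[item_id], respondent.responses[item_id])
        if v is NONGRADABLE:
            continue
        raw += v
        n_graded += 1
    n_items = len(ids)
    coverage = n_graded / n_items if n_items else 0.0

    norm: float | None
    if n_graded == 0:
        norm, valid = None, False
    elif policy.mode is ScoringMode.PRORATED:
        norm = 10.0 * raw / (4 * n_graded)
        valid = coverage >= policy.min_coverage
    else:
        # PUBLISHED / EXACT are defined only at full coverage
        if n_graded == n_items:
            norm = raw * normalization_coefficient(n_items, policy.mode)
            valid = True
        else:
            norm, valid = None, False
    return GroupScore(raw=raw, norm=norm, coverage=coverage,
                      n_items=n_items, n_graded=n_graded, valid=valid)


def score_respondent(respondent: Respondent, bank: ItemBank,
                     policy: ScoringPolicy | None = None) -> ScoreSet:
    """Compute the three outcome scores for a gated respondent."""
    policy = policy or ScoringPolicy()
    return ScoreSet(
        respondent_id=respondent.id,
        mode=policy.mode,
        hearing_related=_score_group(respondent, bank, "hearing_related", policy),
        non_hearing_related=_score_group(respondent, bank, "non_hearing_related", policy),
        speech_perception=_score_group(respondent, bank, "speech_perception", policy),
    )
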