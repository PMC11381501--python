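"""Response coding, filter-question gating, and cohort I/O.

Graded answers use the 0-4 scale; every other outcome ("I don't know",
"Not applicable", "Not required", missing) is a non-gradable category.
Filter questions gate two item blocks: speech-production items H.42-H.48
are required only of speech-impaired respondents, hearing-aid-benefit
items H.87-H.90 only of hearing-aid users.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from enum import Enum

from .item_bank import ItemBank, AID_GATED_ITEMS, SPEECH_GATED_ITEMS

log = logging.getLogger(__name__)

__all__ = [
    "ResponseKind",
    "ResponseValue",
    "Respondent",
    "Cohort",
    "apply_gating",
    "non_gradable_rate",
    "read_cohort",
    "write_cohort",
]


class ResponseKind(Enum):
    GRADED = "GRADED"
    DONT_KNOW = "DK"
    NOT_APPLICABLE = "NA"
    NOT_REQUIRED = "NR"
    MISSING = "MISSING"


@dataclass(frozen=True)
class ResponseValue:
    kind: ResponseKind
    grade: int | None = None

    def __post_init__(self):
        if self.kind is ResponseKind.GRADED:
            if self.grade not in (0, 1, 2, 3, 4):
                raise ValueError(f"grade must be 0..4, got {self.grade!r}")
        elif self.grade is not None:
            raise ValueError(f"{self.kind.name} response cannot carry a grade")

    @property
    def gradable(self) -> bool:
        return self.kind is ResponseKind.GRADED

    @classmethod
    def graded(cls, grade: int) -> "ResponseValue":
        return cls(ResponseKind.GRADED, grade)


DONT_KNOW = ResponseValue(ResponseKind.DONT_KNOW)
NOT_APPLICABLE = ResponseValue(ResponseKind.NOT_APPLICABLE)
NOT_REQUIRED = ResponseValue(ResponseKind.NOT_REQUIRED)
MISSING = ResponseValue(ResponseKind.MISSING)

_TOKEN_TO_VALUE = {
    "DK": DONT_KNOW,
    "NA": NOT_APPLICABLE,
    "NR": NOT_REQUIRED,
    "": MISSING,
}
_VALUE_TO_TOKEN = {
    ResponseKind.DONT_KNOW: "DK",
    ResponseKind.NOT_APPLICABLE: "NA",
    ResponseKind.NOT_REQUIRED: "NR",
    ResponseKind.MISSING: "",
}


@dataclass(frozen=True)
class Respondent:
    """One participant: demographics, audiometry flags, and item responses."""

    id: str
    responses: dict[str, ResponseValue]
    country: str | None = None
    age: float | None = None
    gender: str | None = None
    pta_better: float | None = None
    pta_worse: float | None = None
    per_ear_thresholds: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    hearing_aid_user: bool = False
    speech_impaired: bool = False

    def __post_init__(self):
        if (
            self.pta_better is not None
            and self.pta_worse is not None
            and self.pta_better > self.pta_worse
        ):
            raise ValueError(
                f"{self.id}: pta_better ({self.pta_better}) > pta_worse ({self.pta_worse})"
            )


@dataclass(frozen=True)
class Cohort:
    respondents: tuple[Respondent, ...]
    bank_version: str = "1.0"

    def __post_init__(self):
        ids = [r.id for r in self.respondents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate respondent ids in cohort")

    def __len__(self) -> int:
        return len(self.respondents)

    def __iter__(self):
        return iter(self.respondents)


def apply_gating(respondent: Respondent, bank: ItemBank) -> Respondent:
    """Mark gated-off item blocks NOT_REQUIRED.

    Idempotent.  A graded answer on a gated-off item is overwritten and a
    warning logged — the filter question wins.
    """
    updated = dict(respondent.responses)
    for item_id in sorted(AID_GATED_ITEMS | SPEECH_GATED_ITEMS, key=lambda s: int(s[2:])):
        if item_id not in bank:
            continue
        gate = bank[item_id].gate
        open_ = (
            respondent.hearing_aid_user
            if gate == "HEARING_AID_USER"
            else respondent.speech_impaired
        )
        if open_:
            continue
        current = updated.get(item_id)
        if current is not None and current.gradable:
            log.warning(
                "%s: graded answer %d on gated-off item %s overwritten to NOT_REQUIRED",
                respondent.id, current.grade, item_id,
            )
        updated[item_id] = NOT_REQUIRED
    return replace(respondent, responses=updated)


def non_gradable_rate(cohort: Cohort, item_id: str) -> float:
    """Fraction of the cohort whose response to ``item_id`` is non-gradable."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    n_bad = 0
    for r in cohort:
        v = r.responses.get(item_id)
        if v is None:
            raise KeyError(f"unknown item id {item_id!r} (respondent {r.id})")
        if not v.gradable:
            n_bad += 1
    return n_bad / len(cohort)


_DEMO_COLUMNS = [
    "id", "country", "age", "gender",
    "hearing_aid_user", "speech_impaired", "pta_better", "pta_worse",
]


def _parse_bool(token: str, where: str) -> bool:
    t = token.strip().lower()
    if t in ("1", "true", "yes", "y"):
        return True
    if t in ("0", "false", "no", "n", ""):
        return False
    raise ValueError(f"{where}: cannot parse boolean {token!r}")


def _parse_optional_float(token: str) -> float | None:
    token = token.strip()
    return float(token) if token else None


def read_cohort(csv_source, bank: ItemBank) -> Cohort:
    """Read a cohort from CSV and apply gating.

    Grades are the tokens ``0``..``4``; ``DK``/``NA``/``NR`` code the
    non-gradable categories and an empty cell is a missing response.
    """
    if hasattr(csv_source, "read"):
        rows = list(csv.DictReader(csv_source))
    else:
        with open(csv_source, "r", encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError("cohort CSV has no data rows")

    header = rows[0].keys()
    missing_items = [i for i in bank.item_ids if i not in header]
    if missing_items:
        log.warning("CSV lacks columns for %d items (%s...); coded MISSING",
                    len(missing_items), missing_items[0])

    respondents = []
    for lineno, row in enumerate(rows, start=2):
        responses: dict[str, ResponseValue] = {}
        for item_id in bank.item_ids:
            token = (row.get(item_id) or "").strip()
            if token in _TOKEN_TO_VALUE:
                responses[item_id] = _TOKEN_TO_VALUE[token]
            elif token in ("0", "1", "2", "3", "4"):
                responses[item_id] = ResponseValue.graded(int(token))
            else:
                raise ValueError(
                    f"row {lineno}, column {item_id}: malformed grade token {token!r}"
                )
        r = Respondent(
            id=row["id"],
            country=(row.get("country") or "").strip() or None,
            age=_parse_optional_float(row.get("age", "")),
            gender=(row.get("gender") or "").strip() or None,
            hearing_aid_user=_parse_bool(row.get("hearing_aid_user", ""), f"row {lineno}"),
            speech_impaired=_parse_bool(row.get("speech_impaired", ""), f"row {lineno}"),
            pta_better=_parse_optional_float(row.get("pta_better", "")),
            pta_worse=_parse_optional_float(row.get("pta_worse", "")),
            responses=responses,
        )
        respondents.append(apply_gating(r, bank))
    return Cohort(respondents=tuple(respondents), bank_version=bank.version)


def write_cohort(cohort: Cohort, csv_target, bank: ItemBank) -> None:
    """Write a cohort as CSV (inverse of :func:`read_cohort`)."""

    def _emit(fh):
        writer = csv.writer(fh)
        writer.writerow(_DEMO_COLUMNS + bank.item_ids)
        for r in cohort:
            row = [
                r.id, r.country or "",
                "" if r.age is None else format(r.age, "g"),
                r.gender or "",
                "1" if r.hearing_aid_user else "0",
                "1" if r.speech_impaired else "0",
                "" if r.pta_better is None else format(r.pta_better, "g"),
                "" if r.pta_worse is None else format(r.pta_worse, "g"),
            ]
            for item_id in bank.item_ids:
                v = r.responses.get(item_id, MISSING)
                row.append(str(v.grade) if v.gradable else _VALUE_TO_TOKEN[v.kind])
            writer.writerow(row)

    if hasattr(csv_target, "write"):
        _emit(csv_target)
    else:
        with open(csv_target, "w", encoding="utf-8", newline="") as fh:
            _emit(fh)
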