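"""Instrument structure: the 90-item ICF-based item bank.

The canonical bank (shipped as package data) encodes, per item, the ICF
domain and linked ICF category codes, the construct label (A-G) derived
from exploratory factor analysis, score-group memberships, facilitator
polarity, and filter-question gating.  All group memberships are frozen
in configuration and validated on load; nothing is recomputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Iterable

__all__ = [
    "Item",
    "ItemBank",
    "ItemBankError",
    "load_item_bank",
    "canonical_bank",
    "items_in_group",
    "SCORE_GROUPS",
]

LABELS = ("A", "B", "C", "D", "E", "F", "G")
HEARING_LABELS = frozenset({"A", "C", "E"})
NON_HEARING_LABELS = frozenset({"B", "D", "F", "G"})
#: items in label A whose target sounds are non-speech, excluded from the
#: speech-perception subset
NON_SPEECH_ITEMS = frozenset({"H.25", "H.26", "H.27", "H.29", "H.31"})
MIRRORED_ITEMS = frozenset({f"H.{n}" for n in range(75, 81)})
SPEECH_GATED_ITEMS = frozenset({f"H.{n}" for n in range(42, 49)})
AID_GATED_ITEMS = frozenset({f"H.{n}" for n in range(87, 91)})

#: expected number of items per construct label in the canonical bank
LABEL_COUNTS = {"A": 20, "B": 18, "C": 4, "D": 6, "E": 13, "F": 9, "G": 8}

SCORE_GROUPS = ("hearing_related", "non_hearing_related", "speech_perception", "all_scored")


class ItemBankError(ValueError):
    """Raised when an item-bank configuration violates a structural invariant.

    ``violations`` lists every failed check, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("item bank invalid:\n" + "\n".join(f"- {v}" for v in violations))


def _item_number(item_id: str) -> int:
    return int(item_id.split(".", 1)[1])


@dataclass(frozen=True)
class Item:
    """One questionnaire item."""

    id: str
    icf_domain: str
    icf_codes: tuple[str, ...]
    construct_label: str  # "A".."G" or "NONE"
    efa_factor: int | None
    polarity: str  # STANDARD | MIRRORED
    in_hearing_related: bool
    in_non_hearing_related: bool
    in_speech_perception: bool
    gate: str  # NONE | SPEECH_IMPAIRMENT | HEARING_AID_USER
    short_concept: str = ""

    @property
    def number(self) -> int:
        return _item_number(self.id)

    @property
    def is_scored(self) -> bool:
        return self.construct_label != "NONE"


@dataclass(frozen=True)
class ItemBank:
    """Ordered, validated collection of the instrument's items."""

    items: tuple[Item, ...]
    version: str = "1.0"
    language_tag: str = "en"

    def __post_init__(self):
        object.__setattr__(self, "_by_id", {it.id: it for it in self.items})

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> Item:
        return self._by_id[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    def to_config(self) -> dict:
        """Serializable configuration; ``load_item_bank`` round-trips it."""
        recs = []
        for it in self.items:
            d = asdict(it)
            d["icf_codes"] = list(it.icf_codes)
            if d["construct_label"] == "NONE":
                d["efa_factor"] = None
            recs.append(d)
        return {"version": self.version, "language_tag": self.language_tag, "items": recs}


def _validate(items: Iterable[Item]) -> list[str]:
    items = list(items)
    problems: list[str] = []

    ids = [it.id for it in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        problems.append(f"duplicate item ids: {dupes}")
    if len(items) != 90:
        problems.append(f"{len(items)} items, expected 90")
    expected_ids = {f"H.{n}" for n in range(1, 91)}
    missing = sorted(expected_ids - set(ids), key=_item_number)
    if missing and len(items) == 90:
        problems.append(f"missing item ids: {missing}")

    for it in items:
        if it.construct_label not in LABELS + ("NONE",):
            problems.append(f"{it.id}: unknown construct label {it.construct_label!r}")
        if it.icf_domain not in ("BF", "AP", "EF"):
            problems.append(f"{it.id}: unknown ICF domain {it.icf_domain!r}")
        if it.polarity not in ("STANDARD", "MIRRORED"):
            problems.append(f"{it.id}: unknown polarity {it.polarity!r}")
        mirrored = it.id in MIRRORED_ITEMS
        if (it.polarity == "MIRRORED") != mirrored:
            problems.append(
                f"{it.id}: polarity must be {'MIRRORED' if mirrored else 'STANDARD'} "
                f"(facilitator mirroring applies to H.75-H.80 only)"
            )
        if it.in_hearing_related != (it.construct_label in HEARING_LABELS):
            problems.append(f"{it.id}: hearing-related membership inconsistent with label")
        if it.in_non_hearing_related != (it.construct_label in NON_HEARING_LABELS):
            problems.append(f"{it.id}: non-hearing-related membership inconsistent with label")
        speech = it.in_hearing_related and it.id not in NON_SPEECH_ITEMS
        if it.in_speech_perception != speech:
            problems.append(f"{it.id}: speech-perception membership inconsistent")
        expected_gate = (
            "SPEECH_IMPAIRMENT" if it.id in SPEECH_GATED_ITEMS
            else "HEARING_AID_USER" if it.id in AID_GATED_ITEMS
            else "NONE"
        )
        if it.gate != expected_gate:
            problems.append(f"{it.id}: gate must be {expected_gate}, got {it.gate}")

    from collections import Counter

    counts = Counter(it.construct_label for it in items)
    for lab, want in LABEL_COUNTS.items():
        if counts.get(lab, 0) != want:
            problems.append(f"label {lab}: {counts.get(lab, 0)} items, expected {want}")
    n_hear = sum(it.in_hearing_related for it in items)
    n_non = sum(it.in_non_hearing_related for it in items)
    n_speech = sum(it.in_speech_perception for it in items)
    n_scored = sum(it.is_scored for it in items)
    for name, got, want in (
        ("hearing-related", n_hear, 37),
        ("non-hearing-related", n_non, 41),
        ("speech-perception", n_speech, 32),
        ("scored", n_scored, 78),
    ):
        if got != want:
            problems.append(f"{name} group has {got} items, expected {want}")
    both = [it.id for it in items if it.in_hearing_related and it.in_non_hearing_related]
    if both:
        problems.append(f"items in both score groups: {both}")
    return problems


def load_item_bank(config_source) -> ItemBank:
    """Load and validate an item bank.

    ``config_source`` may be a path to a JSON file, an open file object, or
    an already-parsed configuration mapping.  Raises :class:`ItemBankError`
    naming every violated invariant.
    """
    if isinstance(config_source, dict):
        cfg = config_source
    elif hasattr(config_source, "read"):
        cfg = json.load(config_source)
    else:
        with open(config_source, "r", encoding="utf-8") as fh:
            cfg = json.load(fh)

    items = []
    for rec in cfg["items"]:
        items.append(
            Item(
                id=rec["id"],
                icf_domain=rec["icf_domain"],
                icf_codes=tuple(rec.get("icf_codes", ())),
                construct_label=rec.get("construct_label", "NONE"),
                efa_factor=rec.get("efa_factor"),
                polarity=rec["polarity"],
                in_hearing_related=bool(rec["in_hearing_related"]),
                in_non_hearing_related=bool(rec["in_non_hearing_related"]),
                in_speech_perception=bool(rec["in_speech_perception"]),
                gate=rec.get("gate", "NONE"),
                short_concept=rec.get("short_concept", ""),
            )
        )
    problems = _validate(items)
    if problems:
        raise ItemBankError(problems)
    items.sort(key=lambda it: it.number)
    return ItemBank(
        items=tuple(items),
        version=cfg.get("version", "1.0"),
        language_tag=cfg.get("language_tag", "en"),
    )


def canonical_bank() -> ItemBank:
    """The bundled canonical 90-item bank."""
    ref = resources.files("icfhear.data").joinpath("item_bank.json")
    with ref.open("r", encoding="utf-8") as fh:
        return load_item_bank(fh)


def items_in_group(bank: ItemBank, group: str) -> list[str]:
    """Item ids in a score group, ascending by item number.

    ``group`` is one of ``hearing_related``, ``non_hearing_related``,
    ``speech_perception`` or ``all_scored``.
    """
    if group == "hearing_related":
        sel = [it for it in bank if it.in_hearing_related]
    elif group == "non_hearing_related":
        sel = [it for it in bank if it.in_non_hearing_related]
    elif group == "speech_perception":
        sel = [it for it in bank if it.in_speech_perception]
    elif group == "all_scored":
        sel = [it for it in bank if it.is_scored]
    else:
        raise ValueError(f"unknown score group {group!r}; expected one of {SCORE_GROUPS}")
    return [it.id for it in sorted(sel, key=lambda it: it.number)]
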