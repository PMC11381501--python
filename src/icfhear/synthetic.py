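"""Synthetic cohorts with the statistical structure the pipeline assumes.

Respondents are simulated from a 7-construct latent factor model: each
scored item loads on its construct, the latent value is cut at ordinal
thresholds into a 0-4 hardship grade, and facilitator items are emitted
on the raw (inverted) polarity.  Hearing-loss groups shift the
hearing-related constructs upward with severity, pure-tone averages are
drawn within the class band, and non-gradable responses are injected at
configurable per-item rates.  Ground truth (latents, loadings, group
labels) is returned alongside for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .item_bank import ItemBank, canonical_bank
from .responses import (
    Cohort,
    Respondent,
    ResponseValue,
    DONT_KNOW,
    MISSING,
    NOT_APPLICABLE,
    NOT_REQUIRED,
    apply_gating,
)

__all__ = ["GeneratorConfig", "generate_cohort", "generate_worked_fixture"]

CONSTRUCTS = ("A", "B", "C", "D", "E", "F", "G")
HEARING_CONSTRUCTS = ("A", "C", "E")

#: published subgroup sizes: normal hearing, unaided/aided by HL degree
DEFAULT_SUBGROUP_SIZES = {
    "NH": 58,
    "U_MI": 47, "U_MO": 34, "U_MS": 6,
    "A_MI": 9, "A_MO": 37, "A_MS": 24,
}

DEFAULT_PTA_RANGES = {
    "NH": (-2.0, 20.0),
    "MI": (20.0, 35.0),
    "MO": (35.0, 50.0),
    "MS": (50.0, 65.0),
}

#: latent mean shift per construct for each hearing class (NH baseline 0)
DEFAULT_GROUP_EFFECTS = {
    "NH": {},
    "MI": {"A": 0.9, "C": 0.5, "E": 0.9, "B": 0.5, "G": 0.4, "F": 0.3},
    "MO": {"A": 1.5, "C": 0.8, "E": 1.5, "B": 0.7, "G": 0.55, "F": 0.4},
    "MS": {"A": 2.1, "C": 1.0, "E": 2.1, "B": 0.9, "G": 0.7, "F": 0.5},
}

#: items with elevated not-applicable rates (work/infrastructure concepts)
DEFAULT_ELEVATED_NONGRADABLE = {
    "H.64": 0.15, "H.27": 0.16, "H.63": 0.18, "H.82": 0.21,
    "H.78": 0.19, "H.62": 0.24, "H.81": 0.29,
}

DEFAULT_COUNTRY_MIX = {"Germany": 89, "Egypt": 54, "USA": 72}


def _default_correlations() -> np.ndarray:
    phi = np.full((7, 7), 0.35)
    np.fill_diagonal(phi, 1.0)
    # hearing constructs hang together more tightly
    for a in (0, 2, 4):  # A, C, E
        for b in (0, 2, 4):
            if a != b:
                phi[a, b] = 0.55
    return phi


@dataclass
class GeneratorConfig:
    seed: int = 0
    subgroup_sizes: dict = field(default_factory=lambda: dict(DEFAULT_SUBGROUP_SIZES))
    pta_ranges: dict = field(default_factory=lambda: dict(DEFAULT_PTA_RANGES))
    construct_correlations: np.ndarray = field(default_factory=_default_correlations)
    group_effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_EFFECTS.items()})
    #: reduction of hearing-construct shifts for aided respondents
    aided_relief: float = 0.3
    #: per-item primary loadings; items not listed get a deterministic
    #: default in [0.55, 0.85]
    construct_loadings: dict = field(default_factory=dict)
    #: global ordinal thresholds on the latent scale (strictly increasing)
    ordinal_thresholds: tuple = (0.25, 1.15, 2.1, 3.1)
    #: latent hardship offset for facilitator items, placing raw
    #: facilitator means in the published 2.3-3.4 band
    facilitator_offset: float = 0.5
    nongradable_rate: float = 0.042
    nongradable_jitter: float = 0.01
    #: fraction of respondents with zero non-gradable propensity; the rest
    #: carry multiplier Exp(1/(1-p0)) so the per-item marginal stays at
    #: nongradable_rate while missingness clusters within respondents
    #: (keeps listwise-complete cases available, as in field data)
    nongradable_p0: float = 0.60
    #: fraction of respondents for whom the elevated (workplace-type)
    #: items concentrate their not-applicable responses
    workplace_na_fraction: float = 0.32
    elevated_nongradable: dict = field(default_factory=lambda: dict(DEFAULT_ELEVATED_NONGRADABLE))
    n_speech_impaired: int = 11
    country_mix: dict = field(default_factory=lambda: dict(DEFAULT_COUNTRY_MIX))
    pta_ear_gap_mean: float = 6.1
    pta_ear_gap_sd: float = 5.9
    #: residual noise multiplier; 0 with zero group effects collapses the
    #: generator to identical respondents
    noise_scale: float = 1.0

    def validate(self) -> None:
        if any(v < 0 for v in self.subgroup_sizes.values()):
            raise ValueError("subgroup sizes must be non-negative")
        if sum(self.subgroup_sizes.values()) <= 0:
            raise ValueError("empty cohort requested")
        t = self.ordinal_thresholds
        if any(b <= a for a, b in zip(t, t[1:])) or len(t) != 4:
            raise ValueError("ordinal_thresholds must be 4 strictly increasing cut points")
        phi = np.asarray(self.construct_correlations, dtype=float)
        if phi.shape != (7, 7) or not np.allclose(phi, phi.T):
            raise ValueError("construct_correlations must be a symmetric 7x7 matrix")
        if np.linalg.eigvalsh(phi).min() <= 0:
            raise ValueError("construct_correlations must be positive definite")
        if not 0 <= self.nongradable_rate < 1:
            raise ValueError("nongradable_rate must be in [0, 1)")


def _default_loading(item_number: int) -> float:
    # deterministic spread across the published-looking 0.55-0.85 band
    return 0.55 + 0.30 * ((item_number * 37) % 90) / 89.0


def _class_of(subgroup: str) -> str:
    return "NH" if subgroup == "NH" else subgroup.split("_")[1]


def generate_cohort(config: GeneratorConfig | None = None,
                    bank: ItemBank | None = None) -> tuple[Cohort, dict]:
    """Simulate a cohort; returns (cohort, ground_truth).

    Ground truth carries subgroup labels, latent construct values, the
    item loading map and thresholds used, so recovery can be tested.
    """
    config = config or GeneratorConfig()
    config.validate()
    bank = bank or canonical_bank()
    rng = np.random.default_rng(config.seed)

    subgroups: list[str] = []
    for name, size in config.subgroup_sizes.items():
        subgroups.extend([name] * int(size))
    n = len(subgroups)

    # latent construct values: MVN with group-shifted means
    phi = np.asarray(config.construct_correlations, dtype=float)
    chol = np.linalg.cholesky(phi)
    eta = rng.standard_normal((n, 7)) @ chol.T * config.noise_scale
    cidx = {c: i for i, c in enumerate(CONSTRUCTS)}
    for i, sg in enumerate(subgroups):
        cls = _class_of(sg)
        effects = config.group_effects.get(cls, {})
        aided = sg.startswith("A_")
        for label, shift in effects.items():
            if aided and label in HEARING_CONSTRUCTS:
                shift = max(0.0, shift - config.aided_relief)
            eta[i, cidx[label]] += shift

    # audiometry
    pta_better = np.empty(n)
    for i, sg in enumerate(subgroups):
        lo, hi = config.pta_ranges[_class_of(sg)]
        pta_better[i] = rng.uniform(lo, hi)
    gap = np.abs(rng.normal(config.pta_ear_gap_mean, config.pta_ear_gap_sd, n))
    pta_worse = np.minimum(pta_better + gap, 85.0)

    # speech impairment: spread over NH / unaided / aided as published (1/7/3)
    order = np.argsort(rng.random(n))
    impaired = np.zeros(n, dtype=bool)
    want = {"NH": 1, "U": 7, "A": 3}
    total = config.n_speech_impaired
    got = 0
    for i in order:
        if got >= total:
            break
        key = "NH" if subgroups[i] == "NH" else subgroups[i][0]
        if want.get(key, 0) > 0:
            want[key] -= 1
            impaired[i] = True
            got += 1
    for i in order:  # top up if subgroup quotas could not be met
        if got >= total:
            break
        if not impaired[i]:
            impaired[i] = True
            got += 1

    aid_user = np.array([sg.startswith("A_") for sg in subgroups])

    # per-item latent -> grades
    loadings = {}
    thresholds = np.asarray(config.ordinal_thresholds, dtype=float)
    grades = np.empty((n, 90), dtype=int)
    for j, item in enumerate(bank):
        lam = config.construct_loadings.get(item.id, _default_loading(item.number))
        loadings[item.id] = lam
        if item.construct_label != "NONE":
            base = lam * eta[:, cidx[item.construct_label]]
        else:
            # gated blocks: independent latent, mild hardship
            base = lam * rng.standard_normal(n) * config.noise_scale
        noise = math.sqrt(max(0.0, 1 - lam * lam)) * rng.standard_normal(n) * config.noise_scale
        latent = base + noise
        if item.polarity == "MIRRORED" or item.gate == "HEARING_AID_USER":
            latent = latent + config.facilitator_offset
        hardship = np.searchsorted(thresholds, latent, side="left")
        # facilitator-polarity items are recorded raw (4 = most supportive)
        if item.polarity == "MIRRORED" or item.gate == "HEARING_AID_USER":
            grades[:, j] = 4 - hardship
        else:
            grades[:, j] = hardship

    # countries, cosmetic
    countries = []
    for name, size in config.country_mix.items():
        countries.extend([name] * int(size))
    while len(countries) < n:
        countries.append(next(iter(config.country_mix), "NA"))
    countries = countries[:n]

    # respondent-level non-gradable propensities (missingness clusters
    # within respondents; per-item marginal rates stay on target)
    p0 = config.nongradable_p0
    propensity = np.where(
        rng.random(n) < p0,
        0.0,
        rng.exponential(1.0 / max(1e-9, 1.0 - p0), n),
    )
    wf = config.workplace_na_fraction
    workplace_na = rng.random(n) < wf

    item_list = list(bank)
    respondents = []
    for i in range(n):
        responses: dict[str, ResponseValue] = {}
        for j, item in enumerate(item_list):
            if item.gate == "HEARING_AID_USER" and not aid_user[i]:
                responses[item.id] = NOT_REQUIRED
                continue
            if item.gate == "SPEECH_IMPAIRMENT" and not impaired[i]:
                responses[item.id] = NOT_REQUIRED
                continue
            if item.id == "H.41":
                responses[item.id] = ResponseValue.graded(4 if impaired[i] else 0)
                continue
            elevated = config.elevated_nongradable.get(item.id)
            if elevated is not None:
                rate = (
                    min(0.95, elevated / wf) if workplace_na[i] and wf > 0 else 0.0
                )
            else:
                base = config.nongradable_rate + config.nongradable_jitter * (
                    ((item.number * 13) % 7 - 3) / 3.0
                )
                rate = min(0.9, propensity[i] * base)
            if rate and item.gate == "NONE" and rng.random() < rate:
                u = rng.random()
                responses[item.id] = (
                    NOT_APPLICABLE if u < 0.5 else DONT_KNOW if u < 0.85 else MISSING
                )
                continue
            responses[item.id] = ResponseValue.graded(int(grades[i, j]))
        r = Respondent(
            id=f"R{i + 1:03d}",
            country=countries[i],
            age=float(np.round(rng.uniform(20, 85), 0)),
            gender="male" if rng.random() < 0.56 else "female",
            pta_better=float(np.round(pta_better[i], 1)),
            pta_worse=float(np.round(pta_worse[i], 1)),
            hearing_aid_user=bool(aid_user[i]),
            speech_impaired=bool(impaired[i]),
            responses=responses,
        )
        respondents.append(apply_gating(r, bank))

    cohort = Cohort(respondents=tuple(respondents), bank_version=bank.version)
    truth = {
        "subgroups": list(subgroups),
        "classes": [_class_of(sg) for sg in subgroups],
        "latent": eta,
        "loadings": loadings,
        "thresholds": thresholds.tolist(),
        "pta_better": pta_better,
        "speech_impaired": impaired,
        "hearing_aid_user": aid_user,
        "seed": config.seed,
    }
    return cohort, truth


def generate_worked_fixture(bank: ItemBank | None = None) -> tuple[Cohort, dict]:
    """Deterministic 6-respondent fixture with hand-checkable scores.

    Covers the scale floor, the scale ceiling, a facilitator edge case,
    a gated non-user, a speech-impaired respondent, and a half-coverage
    respondent.  Returns (cohort, expected) where ``expected`` maps
    respondent id to raw scores and flags computed by hand.
    """
    bank = bank or canonical_bank()

    def blank(aid=False, imp=False):
        # zero-hardship baseline: standard items 0, facilitators raw 4
        resp = {}
        for item in bank:
            if item.gate == "HEARING_AID_USER" and not aid:
                resp[item.id] = NOT_REQUIRED
            elif item.gate == "SPEECH_IMPAIRMENT" and not imp:
                resp[item.id] = NOT_REQUIRED
            elif item.polarity == "MIRRORED":
                resp[item.id] = ResponseValue.graded(4)
            else:
                resp[item.id] = ResponseValue.graded(0)
        return resp

    # 1: no hardship anywhere (facilitators maximally supportive, raw 4)
    r1 = blank()

    # 2: maximal hardship (facilitators raw 0 -> coded 4)
    r2 = {}
    for item in bank:
        if item.gate != "NONE":
            r2[item.id] = NOT_REQUIRED
        elif item.polarity == "MIRRORED":
            r2[item.id] = ResponseValue.graded(0)
        else:
            r2[item.id] = ResponseValue.graded(4)

    # 3: facilitator edge case: facilitators answered raw 0 (no support),
    # so only the six mirrored items contribute (6 * 4 = 24 non-hearing
    # raw points)
    r3 = blank()
    for n_ in range(75, 81):
        r3[f"H.{n_}"] = ResponseValue.graded(0)

    # 4: non-user who nevertheless answered H.87 (gating overwrites it)
    r4 = blank()
    r4["H.87"] = ResponseValue.graded(2)

    # 5: speech-impaired, answers the gated block; all scored items at 1
    r5 = blank(imp=True)
    for item in bank:
        if item.gate == "SPEECH_IMPAIRMENT":
            r5[item.id] = ResponseValue.graded(3)
        elif item.gate == "NONE" and item.polarity == "STANDARD":
            r5[item.id] = ResponseValue.graded(1)
        elif item.polarity == "MIRRORED":
            r5[item.id] = ResponseValue.graded(3)  # coded 1
    r5["H.41"] = ResponseValue.graded(4)

    # 6: half coverage on the hearing group: first 19 hearing items graded
    # 2, the remaining 18 "don't know"
    from .item_bank import items_in_group

    r6 = blank()
    hearing_ids = items_in_group(bank, "hearing_related")
    for item_id in hearing_ids[:19]:
        r6[item_id] = ResponseValue.graded(2)
    for item_id in hearing_ids[19:]:
        r6[item_id] = DONT_KNOW

    rows = [
        ("F1", r1, False, False, 5.0),
        ("F2", r2, False, False, 62.0),
        ("F3", r3, False, False, 10.0),
        ("F4", r4, False, False, 25.0),
        ("F5", r5, True, False, 40.0),  # speech-impaired
        ("F6", r6, False, False, 30.0),
    ]
    respondents = []
    for rid, resp, imp, aid, pta in rows:
        r = Respondent(
            id=rid, responses=resp, hearing_aid_user=aid, speech_impaired=imp,
            pta_better=pta, pta_worse=pta + 5.0, country="Germany",
        )
        respondents.append(apply_gating(r, bank))
    cohort = Cohort(respondents=tuple(respondents), bank_version=bank.version)

    expected = {
        "F1": {"raw": (0, 0, 0), "full_coverage": True},
        "F2": {"raw": (148, 164, 128), "full_coverage": True},
        "F3": {"raw": (0, 24, 0), "full_coverage": True},
        "F4": {"raw": (0, 0, 0), "full_coverage": True, "h87_not_required": True},
        "F5": {"raw": (37, 41, 32), "full_coverage": True},
        # of the first 19 hearing items (H.18..H.37) 14 are speech items,
        # so the graded speech raw is 14 * 2 = 28
        "F6": {"raw": (38, 0, 28), "hearing_coverage": 19 / 37, "prorated_norm_hearing": 5.0},
    }
    return cohort, expected
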