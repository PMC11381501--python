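# icfhear

Toolkit for an ICF-based hearing-and-functioning self-assessment
instrument: the 90-item bank, response coding with filter-question
gating, the three outcome scores (hearing-related, non-hearing-related,
speech perception), disability-degree classification, and the full
psychometric validation battery (descriptives, floor/ceiling effects,
Cronbach's alpha, Mann-Whitney U, KMO, Bartlett's sphericity, and
principal-axis factoring with Promax rotation). A synthetic-cohort
generator reproduces the statistical structure the analyses assume, so
every pipeline stage is testable without access to patient data.

## Test

```sh
python -m pytest -q tests/
```

## Library quick start

```python
import icfhear as ih

bank = ih.canonical_bank()                      # 90 validated items
cohort, truth = ih.generate_cohort()            # 215-respondent synthetic cohort
scores = [ih.score_respondent(r, bank) for r in cohort]

t = ih.PAPER_THRESHOLDS["hearing_related"]      # published M/SD cut points
degree = ih.classify_disability(scores[0].hearing_related.norm, t)

from icfhear.psychometrics import cronbach_alpha
res = cronbach_alpha(cohort, ih.items_in_group(bank, "all_scored"), bank)
```

Scoring modes: `published` uses the printed per-point coefficients
(0.067 / 0.061 / 0.0782 — note 0.067 truncates 10/148), `exact` uses
10/(4·n), and `prorated` (default) tolerates non-gradable items and
flags scores below the 80% coverage floor as invalid.

## Command line

```sh
icfhear simulate --seed 1 --out-dir out/          # cohort.csv + ground_truth.json
icfhear score    out/cohort.csv --out-dir out/    # scores.csv
icfhear classify out/cohort.csv --out-dir out/    # degrees.csv + concordance.json
icfhear validate out/cohort.csv --out-dir out/    # descriptives.csv + reliability.json
icfhear efa      out/cohort.csv --out-dir out/    # efa_loadings.csv + efa_summary.json
icfhear pipeline --seed 1 --out-dir out/          # all of the above
```

All commands accept `--seed`, `--config` (YAML/JSON), `--out-dir` and
`--log-level`, and write a manifest with input digests so identical
inputs reproduce byte-identical outputs.

## Layout

- `src/icfhear/item_bank.py` — item structure, canonical bank (JSON in
  `src/icfhear/data/`), validation
- `src/icfhear/responses.py` — response coding, gating, cohort CSV I/O
- `src/icfhear/scoring.py` — facilitator mirroring, raw/normalized scores
- `src/icfhear/classification.py` — PTA classes, disability degrees,
  concordance cross-tabulation
- `src/icfhear/psychometrics.py` — validation statistics and EFA
- `src/icfhear/synthetic.py` — latent-trait cohort generator and the
  hand-checkable worked fixture
- `src/icfhear/cli.py` — command-line pipeline
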