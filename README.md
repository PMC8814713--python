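# amss — Adapted Murine Sepsis Score toolkit

Welfare monitoring in mouse sepsis models (e.g. fecal-induced peritonitis)
traditionally uses the **Murine Sepsis Score (MSS)**: seven observational
items — appearance, level of consciousness, activity, response to stimulus,
eyes, respiration rate, respiration quality — each rated 0–4 by the
experimenter, total 0–28. The **Adapted MSS (A-MSS)** adds three objective,
binned quantitative items — rectal temperature, glycemia, and relative
body-weight loss — extending the scale to 0–40 and making the exam less
subjective and informative earlier in the disease course.

This package is for researchers running murine sepsis experiments who want
to (a) apply the A-MSS rubric reproducibly to longitudinal monitoring data,
(b) derive the standard hematological severity indices (NLR, PLR, MPV/PC,
baseline-relative platelet count), and (c) run the diagnostic-validation
statistics used to establish such a score — ROC analysis with Youden-index
cutoff selection, sensitivity/specificity, Pearson/Spearman correlations,
and two-way (treatment × time) ANOVA with Bonferroni post-tests. A seeded
synthetic-cohort simulator makes the whole pipeline testable without animal
data.

## The score

For one observation, with the seven observational items
$s_1,\dots,s_7 \in \{0,\dots,4\}$:

$$\mathrm{MSS} = \sum_{i=1}^{7} s_i, \qquad
\mathrm{A\text{-}MSS} = \mathrm{MSS} + s_T + s_G + s_W \in [0, 40]$$

where the quantitative items are banded (severity 0–4):

| Item | 0 | 1 | 2 | 3 | 4 |
| --- | --- | --- | --- | --- | --- |
| Rectal temperature (°C) | 36–38 | > 38 | [35, 36) | [34, 35) | < 34 |
| Glycemia (mg/dL) | ≥ 148 | [122, 148) | [58, 122) | (40, 58) | ≤ 40 |
| Weight loss vs baseline (%) | ≤ 5 | (5, 10] | (10, 15] | (15, 20] | > 20 |

Weight loss is relative to each animal's earliest (time-zero) weight. An
animal is called **septic** when its A-MSS total is strictly above the
cutoff (default 3.5, i.e. total ≥ 4). A missing input leaves the affected
item — and therefore the total — undefined; nothing is imputed.

The diagnostic cutoff is chosen on the ROC curve by maximizing Youden's
$J = \text{sensitivity} + \text{specificity} - 1$ over midpoint thresholds,
breaking ties toward higher specificity.

## Worked example

Simulate a cohort with the default study design (7 controls, 8 septic mice,
observed at 0/4/12/24 h), then classify every animal from its 4 h score:

```console
$ amss simulate sim.csv --seed 7
$ amss diagnose sim.csv
Per-mouse classification at 4 h (cutoff 3.5):
        C1  group=control  A-MSS=  1  -> non_septic
        C2  group=control  A-MSS=  1  -> non_septic
        C3  group=control  A-MSS=  0  -> non_septic
        C4  group=control  A-MSS=  0  -> non_septic
        C5  group=control  A-MSS=  1  -> non_septic
        C6  group=control  A-MSS=  0  -> non_septic
        C7  group=control  A-MSS=  2  -> non_septic
        S1  group=sepsis   A-MSS= 10  -> septic
        S2  group=sepsis   A-MSS= 11  -> septic
        S3  group=sepsis   A-MSS= 11  -> septic
        S4  group=sepsis   A-MSS= 13  -> septic
        S5  group=sepsis   A-MSS= 13  -> septic
        S6  group=sepsis   A-MSS= 12  -> septic
        S7  group=sepsis   A-MSS= 12  -> septic
        S8  group=sepsis   A-MSS= 12  -> septic

ROC validation:
  AUC            1.000
  chosen cutoff  6 (Youden J = 1.000)
  sensitivity    100.0 %
  specificity    100.0 %
```

Four hours after induction the simulated septic animals already score 10–13
(driven by rising observational items, early hypoglycemia and mild
hypothermia) while controls sit at 0–2, so the ROC separates the groups
perfectly and the Youden-optimal cutoff (here 6, the midpoint between the
highest control and lowest septic score) calls every animal correctly.
`amss score` writes the per-item breakdown as CSV, and `amss report` emits a
JSON study report (group summaries per timepoint, ANOVA tables, the
correlation panel against 24 h severity markers, and the ROC summary).

The same pipeline is available as a library:

```python
from amss import default_config, generate_cohort, score_cohort, validate_score

cohort = generate_cohort(default_config(seed=7))
scored = score_cohort(cohort)               # one row per observation
report = validate_score(cohort)             # ROC @ 4 h + correlations + ANOVA
print(report["roc"]["auc"], report["cutoff"]["chosen"])
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch:
it generates the default synthetic cohort from the given seed, scores it,
derives the hematological indices, and performs the 4 h ROC validation with
the 24 h correlation panel, printing a summary to stderr and writing the
results JSON to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `amss.model` — domain types (`Observation`, `MouseRecord`, `Cohort`) and
  CSV I/O; missing values are first-class.
- `amss.scoring` — the ten-item rubric, totals, classification, and the
  exportable descriptor table.
- `amss.hematology` — `HematologyPanel` and the derived indices.
- `amss.diagnostics` — ROC/cutoff/confusion metrics, correlations,
  two-way ANOVA with Bonferroni post-tests, and `validate_score`.
- `amss.simulate` — the seeded cohort generator and its configuration.
- `amss.cli` — `amss simulate | score | diagnose | report`.

See `docs/methods.md` for the modelling assumptions, default parameters and
numerical conventions.
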