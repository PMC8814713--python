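# Methods

## The scoring model

The A-MSS is an ordinal composite: seven rater-assigned observational items
(each 0–4) plus three quantitative items obtained by binning rectal
temperature, glycemia and relative body-weight loss into the same 0–4
severity scale. The total ranges 0–40; the observational subtotal (the
classic MSS) ranges 0–28. The score is a plain sum — items are not
weighted — so it inherits the MSS's assumption that item severities are
exchangeable contributions to overall morbidity.

### Band-edge conventions

The printed bin tables for the quantitative items share endpoints between
adjacent bands, so a deterministic convention is required:

- **Temperature.** 36 °C and 38 °C both belong to the healthy band 0,
  because the neighbouring bands are strict on those sides (hyperthermia is
  "> 38", band 2 is "< 36"). Hyperthermia scores 1 — the scorer is
  deliberately non-monotone, reflecting that early fever is less ominous
  than hypothermia, which escalates to 4 below 34 °C.
- **Glycemia.** 148 mg/dL appears in both band 0 ("≥ 148") and band 1
  ("≤ 148"); we resolve it to the *healthier* band (score 0), the
  conservative choice that never inflates severity on a typographic
  overlap. By the same logic the band-3/band-4 edge at 40 mg/dL is scored 4
  only at "≤ 40", leaving band 3 the open interval (40, 58).
- **Weight loss.** Bands are left-open/right-closed — exactly 5 % scores 0,
  exactly 20 % scores 3 — the only reading consistent with the strict
  "> 20" of band 4. Negative loss (weight gain) scores 0.

The weight-loss baseline is each animal's **earliest** observation (time
zero in the intended design). Comparing to the previous timepoint instead
would be a defensible alternative; baseline-relative was chosen because the
monitoring design measures animals "before" induction, and it makes the
item monotone in cumulative catabolic loss.

### Missing data

Missingness is never imputed. A missing measurement leaves its item
undefined, and any undefined item leaves the A-MSS total undefined
(`complete = False`): a partial sum is not comparable on the 0–40 scale and
silently substituting 0 would bias totals toward health. The same contract
applies to hematological ratios (an index with a missing input or a zero
denominator is undefined and flagged, not zero, and not an exception).

### Classification

An animal is septic when its A-MSS total is **strictly above** the cutoff.
The default cutoff 3.5 sits between the integer totals 3 and 4, so the
boundary convention is unobservable on real scores; it matters only for
non-integer extensions and is documented rather than asserted.

## Diagnostic statistics

- **ROC.** Candidate thresholds are midpoints between adjacent distinct
  pooled scores plus ∓∞ sentinels. Sensitivity at cutoff *c* is the
  fraction of septic animals with score > *c*; specificity the fraction of
  controls with score ≤ *c*. The AUC is the trapezoidal area under the
  (1 − specificity, sensitivity) polyline, which equals the Mann–Whitney
  concordance with ties counted ½ (asserted against a brute-force all-pairs
  oracle in the tests).
- **Cutoff selection.** "Best balance of sensitivity and specificity" is
  operationalized as maximum Youden J = sens + spec − 1, ties broken toward
  higher specificity (a false septic call wastes an animal; a missed one is
  caught at the next timepoint), then toward the lower threshold. On
  integer scores this yields cutoffs on the half-integer grid (3.5, 5.0,
  …).
- **Correlation.** Pearson is the product-moment coefficient; Spearman is
  Pearson on midranks. Two-sided p-values use the t transform
  t = r·√((n−2)/(1−r²)) with n−2 df; |r| = 1 maps to p = 0. Zero variance
  in either vector is an error (r undefined), not NaN propagation. The
  method is caller-chosen; no automatic normality-based switching.
- **Two-way ANOVA.** Fixed-effects treatment × time decomposition with
  interaction. Sums of squares are Type-III-style model comparisons on a
  sum-coded (effects-coded) design matrix, i.e. unweighted cell means —
  chosen because the 7-vs-8 design is unbalanced and this convention tests
  each effect adjusted for the others. On balanced data it reduces to the
  textbook partition SS_total = SS_A + SS_B + SS_AB + SS_within (asserted
  in tests, along with agreement with an independent GLM oracle). Zero
  within-cell variance raises a degenerate-data error since F is undefined.
- **Post-tests.** The Bonferroni family is the set of treatment contrasts
  within each time level (4 comparisons on the default grid), using the
  pooled error term; adjusted p = min(1, raw p × #comparisons). p-values
  are two-sided throughout.

`validate_score` ties these together: ROC of the A-MSS at an early
timepoint (default 4 h) against group membership, confusion metrics at the
chosen and at the default cutoff, correlations of the early A-MSS against
late (24 h) hematological severity markers (lymphocytes, WBC, platelets,
NLR) and of the late scores against glycemia, temperature and weight.
Weight enters the correlation panel as *percent of baseline weight*
(declining with severity), so all three physiological correlations are
expected negative — matching the sign convention of the reported findings.

## The synthetic cohort generator

No animal-level dataset is publicly available for this design, so the
generator stands in. It emulates the *stated* two-arm study — control n = 7
vs sepsis n = 8, observed at 0/4/12/24 h — with the qualitative dynamics
reported for fecal-induced peritonitis within 24 h:

| variable | baseline (mean ± SD) | sepsis trajectory |
| --- | --- | --- |
| weight | 25 ± 1.5 g | −3 %, −8 %, −15 % at 4/12/24 h |
| temperature | 37.2 ± 0.25 °C | −1.5, −2.5, −4.0 °C (below 34 °C at 24 h) |
| glycemia | 160 ± 8 mg/dL | −50, −90, −125 mg/dL (≤ 40 band at 24 h) |
| neutrophils | 1.2 ± 0.3 ×10³/µL | +1.0, +2.8, +0.3 (12 h peak, return to near-baseline) |
| lymphocytes | 6.0 ± 0.8 ×10³/µL | −1.0, −2.5, −4.0 (24 h lymphopenia) |
| monocytes | 0.5 ± 0.12 ×10³/µL | −0.05, −0.15, −0.3 |
| platelets | 1100 ± 90 ×10³/µL | −150, −350, −600 |
| MPV | 5.5 ± 0.3 fL | no effect within 24 h |

Baselines are typical for adult C57BL/6 mice; effect magnitudes were chosen
once to land squarely inside the rubric bins that the study narrative
implies (hypoglycemia into the ≤ 40 band, hypothermia below 34 °C, > 10 %
weight loss) and are package constants, not tuning knobs. WBC is **derived**
as neutrophils + lymphocytes + monocytes + a small "unclassified" component
(0.4 ± 0.1), which guarantees the panel's internal-consistency invariant by
construction; its decline at 24 h (leukopenia) follows from the
lymphopenia/monocytopenia.

Observational items come from a latent-severity model: the sepsis arm
follows a severity curve (0, 1.2, 2.2, 3.0 at 0/4/12/24 h, linearly
interpolated; controls at 0) and each item is
clamp(round(severity + item offset + N(0, 0.35)), 0, 4). A shared latent
severity induces the inter-item correlation the MSS assumes; the 0.35 item
noise makes occasional 1s in healthy controls (rater disagreement) without
pushing control totals near the diagnostic cutoff.

Noise is truncated Gaussian around piecewise-linear group means — a
phenomenological model, not pathophysiology. Consequences for what a green
test establishes: the pipeline tests verify that scoring and statistics
*recover a constructed signal* (direction, separation, calibration under a
null with zero effects), not that the A-MSS performs at any particular
level on real animals. Real data differ in ways the generator ignores:
mortality/censoring, inter-variable correlation beyond the shared severity,
non-Gaussian tails, rater drift, and day-night rhythms in temperature and
glycemia.

Determinism: a single integer seed drives everything; each variable draws
from an independent child stream keyed by seed + CRC-32 of the variable
name, so adding a simulated variable never perturbs existing ones, and
identical (config, seed) pairs produce byte-identical CSV. Generated values
are rounded to instrument-realistic precision (weights 0.01 g, temperature
0.1 °C, glycemia 1 mg/dL), which also makes CSV round-trips exact.

## Numerical and interface conventions

- CSV floats are written with shortest round-trip (`repr`) formatting;
  empty cell = missing, never 0.
- Timepoints are not restricted to the 0/4/12/24 h grid; the grid is
  metadata, and trajectories/severity interpolate linearly off-grid.
- CLI exit codes: 0 success, 2 user/data error, 1 internal error. Every run
  writes a JSON manifest (command, input digest, seed, package version,
  timestamp); data outputs are byte-deterministic for fixed inputs and
  seed, the manifest's timestamp is not.
- Reports are JSON-first; plotting is out of scope.

## Known limitations

- The observational items must be rater-assigned; there is no automated
  scoring from video or sensors.
- The ANOVA is a fixed-effects factorial on repeated measures — it ignores
  within-animal correlation (no mixed-model or repeated-measures variant),
  matching the analysis style the score was validated with.
- No AUC confidence intervals (DeLong) and no normality screening gate.
- "Relative platelet count" is interpreted as percent of each animal's
  baseline platelet count; a composition-based reading (platelet fraction
  of total cells) would be a one-line strategy swap in
  `amss.hematology.derive_indices`.
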