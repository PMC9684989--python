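# Methods

## The diagnostic model

The classifier is a deterministic, ordered rule system, not a fitted model.
Each rule is a conjunction of *required* findings; a record is assigned the
label of the first rule whose requirements it satisfies (first-match-wins),
so ties are impossible by construction and classification is a pure, total
function of the feature vector. *Supportive* findings (rheumatologic history
for fibrosing NSIP; skin erythema, arthralgia and significant
lymphadenopathy for sarcoidosis; fibro-calcific consolidation for PMF; a
rapidly progressive course for PPFE) never change the label — they only
upgrade the trace's confidence note — which gives the engine a monotonicity
guarantee that is enforced by a property test.

Ordering choices that matter:

* Irradiation history with field-confined fibrosis decides first, because a
  minority of irradiation scars are basal and would otherwise leak into the
  interstitial branch.
* Within the upper-lobe branch, TB stigmata are tested before the
  platy-thorax sign, so platy-thorax only decides when TB evidence is
  absent. This reproduces the algorithm's known confusion direction
  (atypical post-TB read as PPFE) rather than hiding it.
* The "head cheese" sign alone suffices for chronic HP; the crazy-paving
  route additionally requires at least one supportive exposure/laboratory
  finding. This keeps the NSIP↔HP confusion pattern of the validation
  cohort reproducible in both directions.
* Records with neither upper nor lower lobar predominance return
  INDETERMINATE; the engine does not guess.

The malignancy overlay is independent of the terminal rule: T2
hyperintensity together with DWI restriction, **or** SUVmax above the
threshold (default 3.0), flags scar carcinoma when the final label is
post-TB and metastasis when it is post-irradiation. The OR (rather than
AND) combination reflects that each modality is treated as an independent
malignancy predictor. When the predictors fire under any other label the
flag stays NONE and the trace carries a review note.

Tri-state laboratory and MRI fields (`true` / `false` / `not_done`)
preserve "test not performed" explicitly. A `not_done` value never
satisfies a criterion and is never evidence against one.

## Synthetic cohorts: what they emulate, and what they do not

No patient-level data are available, so the generator reconstructs the two
study cohorts from their published summary statistics.

**Derivation cohort (n = 150).** Disease sizes 34 UIP/IPF, 19 fibrosing
NSIP, 16 chronic HP, 2 PPFE, 16 sarcoidosis, 11 PMF, 21 post-TB, 31
post-irradiation. For every feature row of the published prevalence table
the *integer count* is authoritative (percentages are derived); features at
100%/0% prevalence are profile constants, intermediate features carry their
printed count. Quantities reported only in prose are modelled with the
prose values: 48/150 smokers (16/21 in post-TB, the remainder spread
8/5/4/0/4/3/8 over the other profiles), 92 male/58 female, rapidly
progressive course in the 2 PPFE and 3 post-irradiation patients, ages
33–76. Malignancy complicates 7/21 post-TB (scar carcinoma) and 8/31
post-irradiation (metastasis) patients and forces the full MRI/PET triad.

**Validation cohort (n = 100).** True-label sizes 23/19/18/17/14/6/3.
Every patient carries the canonical (textbook) profile of their disease
except six atypical patients, reconstructed as the minimal profiles
consistent with the documented misclassification directions: three chronic
HP patients without head-cheese or crazy paving but with traction
bronchiectasis and unrevealing laboratories (read as NSIP); one NSIP
patient with a head-cheese sign (read as HP); two post-TB patients with
platy-thorax and no TB stigmata (read as PPFE). One post-TB and one
post-irradiation patient carry a malignancy overlay.

**Generation modes.** `exact_counts` (default) allocates exactly the
declared count of positives per feature — the seed only permutes which
patients receive them — so every downstream prevalence, chi-square and
confusion count is deterministic. `bernoulli` draws each feature
independently with probability count/n, for sampling-variability studies.
The mutually exclusive lobar-predominance pair is drawn as a single
three-way categorical so marginals are preserved without invalid records.
Per-profile random substreams are derived from the master seed and a hash
of the disease name, so adding a profile never perturbs the others.

**Limitations.** Only marginal prevalences are published, so features are
generated independently within a disease except where a printed rule forces
dependence (the malignancy triad). Real cohorts have correlated features
(e.g. cavitation and tree-in-bud co-occur in reactivated TB), richer
feature noise, and inter-reader variability in the CT flags themselves.
Passing tests therefore demonstrate that the pipeline reproduces the
published numbers under the published summary statistics — not that the
algorithm would achieve the same operating characteristics on new patients.

## Statistical conventions

* **Association tests.** One-vs-rest Pearson chi-square on 2×2 tables
  (disease vs all other diseases × feature present/absent), 1 df, no
  continuity correction by default; Yates correction and
  Bonferroni/Benjamini–Hochberg multiplicity adjustment are available by
  flag but off by default, matching the original analysis. This
  construction reproduces every non-extreme published p-value to its
  printed precision (e.g. 0.007, 0.004, 0.049, 0.6, 0.17, 0.035, 0.058,
  0.93), which is the evidence for adopting it. A handful of cells printed
  "< 0.001" are inconsistent with their own printed counts under this (or
  any adjacent) test — most notably traction bronchiectasis in post-TB,
  18/21 vs 84/129, which gives p = 0.061; the implementation reports the
  computed value. Cells are reported as not applicable when the feature
  was not performed for any patient of the disease, or when a table margin
  is zero. Display follows the source convention: three decimals with a
  "< 0.001" floor.
* **Confidence intervals.** Exact two-sided Clopper–Pearson, computed from
  beta quantiles: lower = B(α/2; s, n−s+1), upper = B(1−α/2; s+1, n−s),
  with closed forms (α/2)^(1/n) at the s = n boundary and the mirrored form
  at s = 0. Adopted because it reproduces the published boundary intervals
  (85.18% for 23/23, 15.81% for 2/2) to the printed precision; the test
  suite checks it against a brute-force inversion of the exact binomial
  test over a p-grid of step 1e-5 for all n ≤ 120. Two published CI bounds
  do not reproduce under any consistent n (the 14/14 sensitivity lower
  bound prints 75.29%, which is the 13/13 value; the 86/86 specificity
  lower bound prints 95.85%, the 87/87 value); the implementation reports
  the computed 76.84%/95.80%.
* **Diagnostic metrics.** Ratios with zero denominators (e.g. sensitivity
  of a disease absent from the cohort) are undefined and rendered "NA",
  never 0 or 1. Rendered tables show one-decimal percentages and
  three-decimal balanced accuracy; all comparisons in tests round the
  unrounded value. One published NPV (post-TB, 97.7%) differs from the
  computed 83/85 = 97.647% → 97.6% in the last digit; the computed value is
  reported.
* **Problem sizes.** All computations are desk-scale: the cohorts are 150
  and 100 patients as published, the chi-square batch covers ~60 cells,
  and the CI cross-check sweeps all (s, n) with n ≤ 120; the full test
  suite and the acceptance script each run in seconds.

## Design notes

* The patient schema keeps lobar predominance as two mutually exclusive
  booleans (validated) rather than one 3-valued field, so prevalence
  bookkeeping maps one-to-one onto published feature rows; "no clear
  predominance" is representable and routes to INDETERMINATE.
* Cohort files are plain UTF-8 CSV (fixed column order, `true`/`false`/
  `not_done` tokens) or JSON; writes are byte-deterministic and
  `read(write(X)) == X` is a tested property. Unknown columns are rejected
  unless a lenient flag is passed.
* The rule engine is also exposed as an sklearn-style estimator
  (`StepwiseDiagnosisClassifier` with `fit`/`predict`/`get_params`), which
  makes it composable with pipeline and model-selection tooling; `fit`
  only validates input, since the rules are fixed by design.
* The classifier never reads the ground-truth columns; a leakage-guard test
  wipes and scrambles them and asserts identical predictions.
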