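# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Questionnaire scoring

Items are Likert-type ordinal codes. Scoring is entirely key-driven: each
item carries a section, an optional wellbeing sub-scale, its ordered set
of allowed codes, a reverse-coding flag and its instrument version. A
section score is the sum of reverse-adjusted codes over *answered* items;
a section with no answered items is missing, never zero, and no
imputation or proration is applied — instead a per-section completeness
fraction is reported and downstream steps use complete-case analysis.
Positively worded wellbeing items ("I feel very energetic in general")
are reverse-coded so higher always means a presentation more consistent
with low energy availability.

The exact wording and code ranges of the deployed instrument are a
configuration concern; the shipped default key has 29 scored items with
codes 0–3 organised to match the instrument's published score structure
(dizziness, gastrointestinal, thermoregulation, injury/illness items
4A–4F, wellbeing with fatigue / poor-fitness / sleep / poor-recovery /
mood / low-energy sub-scales, version-2 sex-drive items 6A–6D). Keys can
be loaded from YAML to rescore a revised instrument.

Composites:

* **EHMC score** — sum of the nine exercise-hypogonadal-male-condition
  constituents (general sex drive, morning-erection frequency and change,
  plus six energy/wellbeing statements); missing if any constituent is.
* **Low sex drive** — true iff item 6A ≥ 2, or 6C ≥ 2 together with
  6D ≥ 1; structurally missing for version-1 respondents.
* **Weight flux** — self-reported highest minus lowest body weight at
  current height (not measured mass); a highest value below the lowest
  one is rejected as a data-entry swap rather than silently negated.

## Clinical derivation and the case definition

* Abbreviated Weir (no urinary nitrogen): kcal/min = 3.941·V̇O₂ +
  1.106·V̇CO₂, converted at 4.184 kJ/kcal. A respiratory quotient outside
  [0.6, 1.3] warns but does not fail.
* Cunningham predicted RMR: 500 + 22·FFM (kcal/day); the FFM→0 intercept
  is outside the physiological domain and documented as a formula limit.
* RMR ratio = measured (kJ/day) / predicted (converted to kJ/day). "Low"
  uses fixed per-method cutoffs (< 1.11 first principles, < 0.88
  metabolic cart), reflecting systematic differences between methods;
  both cutoffs sit near each method's lowest sample quartile.
* Free testosterone solves the two-binding-protein mass-action system
  (albumin Ka = 3.6×10⁴ L/mol, SHBG Kt = 1×10⁹ L/mol, albumin molar mass
  69 kg/mol, default 43 g/L when unmeasured) via the numerically stable
  positive root of N·Kt·FT² + (N + Kt·(SHBG − TT))·FT − TT = 0 with
  N = 1 + Ka·[Alb]. The tests verify it against an independent bisection
  solve to well below 1e-6 relative error and check monotonicity in each
  argument.
* Blood "low" for the indicators means *below the lowest quartile of the
  per-site reference range*, low + 0.25·(high − low); fixed fallback
  cutoffs (T₃ < 3.5 pmol/L, total testosterone < 16 nmol/L, free
  testosterone < 333 pmol/L) apply when no site range is configured. The
  shipped defaults include example Scandinavian-laboratory free-T₃ ranges
  (3.5–6.5 pmol/L, quartile 4.25) because site quartiles, not the
  fallback, are the primary mechanism in multi-centre data. IGF-1 uses
  age-banded ranges (defaults: 18–30 y 13–55, 30–50 y 12–50 nmol/L).
* The cortisol:insulin ratio is computed exactly as conventionally
  reported — cortisol in nmol/L over insulin in pmol/L, threshold 26.6 —
  without unit harmonisation, and the cortisol composite is one secondary
  indicator (cortisol > 550 nmol/L OR ratio > 26.6). Total and free
  testosterone likewise form a single primary indicator via disjunction.
* All cutoffs are strict inequalities: a value equal to a printed cutoff
  is never low/high.
* Disjunctive indicators with partially missing inputs: met if any branch
  is met; not met if at least one branch is evaluable and none met;
  missing only when nothing can be evaluated.
* Classification: excluded if ≥ 3 indicators missing including ≥ 1
  primary; else case if ≥ 2 primary or ≥ 3 indicators overall are met;
  else control. The classifier is verified against exhaustive enumeration
  of all 3¹⁰ status assignments.

## Validation statistics

* **Reliability**: single-measure two-way mixed-model ICC, consistency
  form ICC(3,1) = (MS_subjects − MS_error)/(MS_subjects + MS_error) for
  k = 2 occasions — the standard choice for a 14-day test–retest of a
  fixed instrument, invariant to an occasion mean shift. An
  absolute-agreement variant is available behind a flag. Confidence
  intervals use the exact F-based interval; simulated at the reliability
  design (n = 42, target ICC 0.71) its empirical coverage is ≈ 94–95%.
  Zero between-subject variance returns a defined 0 with a warning.
  Items whose ICC falls below a cutoff (default 0.50) are removed from
  scoring, and the removal is logged.
* **Association screen**: for every screening variable × clinical outcome
  combination, OLS (continuous) or logistic (binary flag) regression of
  the outcome on the variable adjusted for age, BMI, elite status and —
  only when more than one centre is present in the rows used — centre as
  a categorical. Complete-case per pair with per-fit n reported. The
  screen is deliberately *unadjusted* for multiplicity (per-test
  p < 0.05); the report prints the number of tests so the false-positive
  burden is visible. Exactly collinear covariates are dropped with a log
  entry; logistic separation yields a flagged result, not an exception.
  The screen's binary "low"/"high" outcome flags are the *empirical*
  per-site lowest/highest quartile of observed results — a different
  mechanism from the reference-range quartiles of the case definition,
  and both are implemented.
* **ROC/Youden**: the score orientation is fixed (higher = adverse; no
  auto-flip). Candidate thresholds are midpoints between consecutive
  distinct observed scores — every real operating point; the degenerate
  call-everyone/no-one extremes are not candidates — so integer scores
  yield thresholds on the half-integer grid. Ties in J break towards
  higher specificity, then the lower threshold. A variable is retained
  when its Youden-point sensitivity is ≥ 60% (boundary inclusive) for at
  least one associated outcome.
* **Case–control comparison**: pooled-variance Student t (df =
  n₁ + n₂ − 2). The pooled form was chosen because recomputing the
  published low-sex-drive row from its printed summaries gives ≈ 0.0157
  (pooled) against the printed 0.0160, whereas Welch gives ≈ 0.0285.
  `pooled_t_from_summary` reproduces a raw-data t-test exactly on
  moment-matched data, which makes printed summary tables re-checkable.

## Synthetic cohort generator

A standard-normal latent severity z per athlete drives every injected
signal. Each marker is mean + sd·(λ·z + √(1−λ²)·ε), so configured
marginal means/SDs are preserved exactly regardless of the loading λ;
ordinal item codes come from thresholding a latent standard-normal
response at the quantiles of configured code frequencies. Case prevalence
is *not* a dial: it emerges from applying the indicator thresholds to the
generated markers.

Defaults encode the published multi-centre study conditions: n = 310 with
a 183/127 version split, four centres, marker marginals from the
published cohort table (e.g. total testosterone 19.8 ± 5.8 nmol/L, T₃
5.3 ± 0.8 pmol/L, cortisol 461.5 ± 127.5 nmol/L), an RMR-ratio
two-method mixture (25% first-principles 1.19 ± 0.12, 75% metabolic cart
0.95 ± 0.10, so each method's lowest quartile sits near its fixed
cutoff), SHBG 34 ± 10 nmol/L chosen so the Vermeulen free-testosterone
cohort mean lands near the published 425 pmol/L, and block-wise
missingness with per-centre rates mimicking sites that did not run an
assay (insulin and SHBG panels are structurally version-2 only).
Severity loadings (endocrine/RMR/BMD markers ≈ −0.45…−0.6, cortisol
+0.5, sex-drive items 0.35–0.5, weight flux 0.48) are calibration
choices fixed once against the published case/control separations and
group means (control testosterone ≈ 21.2 nmol/L, low-sex-drive
prevalence ≈ 24%, weight-flux group means ≈ 10.2 vs 8.1 kg, roughly a
quarter to a third of classifiable athletes as cases); inter-marker
correlations beyond the single factor are not represented.

What the generator does **not** emulate: real inter-assay biases, skewed
or heavy-tailed marker distributions (real low-T₃ prevalence arises
partly from distributional shape the Gaussian model lacks — the default
prevalence of cases is ≈ 27% against the published 32%), informative
missingness, and item-level response styles. Passing tests on these
cohorts therefore establish the *procedures* (scoring rules, thresholds,
estimators, retention logic) and the qualitative headline — the sex-drive
score as the only discriminating section — not field performance of the
instrument.

## Numerical and design notes

* kcal↔kJ conversion uses the thermochemical 4.184 throughout; it affects
  the RMR ratio in the third decimal at most.
* The association screen's regressions are fit by statsmodels; the
  t-tests, ICC, ROC search, Weir/Cunningham/Vermeulen derivations and the
  classifier are authored here and each is tested against an independent
  oracle (moment-matched raw-data t-tests, pingouin's ICC table, a dense
  brute-force threshold scan and scikit-learn's ROC curve, a bisection
  mass-action solve, exhaustive enumeration).
* Reports are deterministic given inputs (fixed column order; the run
  manifest records config digests and decision logs; a timestamp is
  written only on request so reruns are byte-identical).
* Simulation-based checks use 200 pipeline replicates (500 for the
  reliability coverage and ROC oracle sweeps) at the published cohort
  size, which resolves the majority-vote headline and coverage bounds
  comfortably on a single CPU.
* Known limitations: the null-cohort retention check documents that a
  multiplicity-unadjusted screen over ~200 tests retains at least one
  variable by chance in most runs — an inherent property of the screening
  design, reported rather than corrected; per-item ICCs treat ordinal
  codes as interval-scaled; the logistic screen reports Wald inference,
  which is anti-conservative near separation (flagged per fit).
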