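# Methods

## The instrument

The RAI-ICD is a deficit-accumulation frailty score computed from
ICD-10-CM-coded hospital discharge data. Ten parameters enter: age and sex
(taken from demographic fields) and eight diagnosis-code-derived deficits —
unintentional weight loss, poor appetite, congestive heart failure,
shortness of breath, kidney failure, cancer, functional status
(independent / partially dependent / totally dependent) and cognitive
decline. Institutional living status, part of the parent RAI instruments,
has no usable counterpart in discharge data and is omitted.

A parameter is present when **one or more** of its mapped codes appears in
any diagnosis slot. Malignant-neoplasm codes (C00–C96) carry a severity
tier — severe, moderate or mild, anchored on 5-year survival — and the
instrument's final cancer parameter definition counts only the severe
categorization (the tiered alternatives remain available for
model-selection experiments; `cohort.CANCER_DEFINITIONS`).

The score is additive with two interactions stored as total-cell grids:

```
S = A(age band, cancer) + m·[male] + Σ_d w_d·[deficit d] + F(functional status, cognitive decline)
```

With the packaged default table the attainable range is 0–81 (verified by
exhaustive enumeration in the test suite), and scores stratify as robust
(<27), normal (27–35), frail (36–45), very frail (>45). Very frail is
encoded as `score ≥ 46`, i.e. the half-open integer reading of ">45".

## Mortality ascertainment

In-hospital death is a composite: discharge disposition *died* **or** an
assigned comfort-care transition code (Z51.5). Both triggers are recorded
(`source ∈ {disposition, comfort_care_code, both}`) and a
`disposition_only` switch reproduces the sensitivity-analysis variant that
ignores the code arm. Dispositions other than *died* are collapsed to
alive; transfer destinations are not modeled.

## Code map

The map is data, not code: a YAML file with one block per parameter, a
tiered cancer block, and a version label; 3–4-character patterns match all
ICD-10-CM descendants (prefix mode), fully specified codes match exactly.
Tier conflicts resolve to the most severe matched tier (monotone risk
ordering). Within-parameter duplicate patterns, cancer patterns outside
C00–C96, and overlap between the partial- and total-dependency pattern
sets are rejected at load.

**The packaged default map is a synthetic reconstruction.** The
instrument's official 323-code listing is distributed under a data license
and is not redistributed here. `codemap_synthetic_v1.yaml` assembles
clinically plausible ICD-10-CM families per parameter (e.g. R63.4/R64 and
the E40–E46 malnutrition block for weight loss; the I50 family plus
hypertensive-heart-failure codes for CHF; dementia codes F01–F03/G30/G31
for cognitive decline; Z74/R26/R53 dependence and mobility codes for
functional status; a tiered C00–C96 enumeration for cancer) and matches
the official list's structure and exact size of 323 distinct codes, so
structural checks and the full pipeline are exercised faithfully. Scores
computed with it on real data are *not* the published instrument; users
holding the licensed list can transcribe it into the same YAML format and
pass it anywhere a map is accepted. A tiny `codemap_demo.yaml` supports
documentation and quick tests.

## Derivation

`FrailtyDerivationModel` fits a maximum-likelihood logistic regression of
death on the parameters with the two interactions (age × cancer as
`(age−18)·cancer`; functional status × cognitive decline as dummy
products). Survey weights enter as relative frequencies — normalized to
mean 1 so estimates are invariant to rescaling while the sandwich variance
reflects the actual sample size — with a heteroskedasticity-robust (HC1)
or cluster-robust covariance. Full Taylor-linearized stratified-design
variance is out of scope: strata rarely move point estimates, and the
instrument needs only coefficients.

Age encoding defaults to **continuous-in-years** (the near-linear 0→38
progression of the published age points supports a linear fit); the age
grid is then tabulated at band representatives (18 for ≤19, midpoints for
interior bands, 100 for ≥100). A categorical-band encoding is available
(`age_encoding="categorical"`); it costs considerable precision in the
sparsely populated young bands and keeps the age × cancer interaction
continuous either way.

**Integerization.** Each term's points are `round(c·β)` relative to its
reference level (age 18, female, no deficits, independent, no cognitive
decline); interaction grid cells are assembled as total points
(`round(c·(β_fs + β_cog + β_fs:cog))`, and analogously for age × cancer).
Negative assembled cells are floored at 0 with a warning, preserving the
all-non-negative table structure. The scale constant `c` defaults to the
auto rule `c = 1/min positive β`, which maps the smallest positive effect
to exactly one point — consistent with poor appetite carrying 1 point in
the published table. Guards: perfect separation raises a named error;
zero-variance covariates are dropped with a warning and contribute 0
points.

**Cancer-definition selection** refits the model under each tier-set
definition (severe / severe+moderate / all) on a cohort built with full
tier information, and picks the definition maximizing the C statistic,
with mean decision-curve net benefit over a small threshold-probability
grid as tie-break, then declared order.

## Calibration

* **Projected mortality**: weighted logistic fit of death on the integer
  score; `p̂(k) = expit(a + b·k)` evaluated at every integer with
  delta-method CIs.
* **Per-integer scan**: for every k in 0..max attainable, treating
  `score ≥ k` as the positive call, the table reports weighted
  TP/FP/FN/TN, sensitivity, specificity, PPV, NPV, `F1 = 2TP/(2TP+FP+FN)`,
  and `MCC = (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`, plus
  weighted observed mortality at k (logit-normal CI via the Kish effective
  n) and the cumulative weighted proportion with score ≤ k. Zero
  denominators yield NaN (undefined), never 0.
* **Thresholds**: the frailty threshold is the smallest integer whose
  projected mortality reaches 2× the overall weighted mortality m̄
  (implemented as the first crossing of exactly 2×: deterministic and
  reproducible), very frail the smallest reaching 4×, and the robust/
  normal boundary sits one above the largest integer with projected
  mortality below m̄. The rules apply to the smoothed projection by
  default (`basis="observed"` switches to raw per-integer mortality); the
  F1 and MCC at the frailty threshold are reported alongside, so either a
  ratio-rule or a max-F1 reading of the threshold can be audited from the
  same table. Both thresholds and the whole table are invariant to
  rescaling all weights by a constant.
* **Discrimination**: the C statistic is the weighted concordance
  probability (ties ½), computed by an O(n log n) cumulative-mass sweep,
  with a stratified bootstrap CI (deaths and survivors resampled
  separately; 200 seeded resamples by default). Tests verify exact
  agreement with an all-pairs oracle and with an external AUROC
  implementation.
* **Decision curve**: `NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)`.
* **Convergent validity**: Spearman rank correlation (average ranks on
  ties) with a seeded bootstrap CI; constant inputs are reported as
  undefined rather than raising.
* **Category outcomes**: weighted n/%, elective %, mortality % with CI,
  and weighted means with SEs for length of stay and charges, per
  category; empty categories emit n = 0 rows with NaN statistics.

## Synthetic data generator

The generator emulates the instrument's analysis population — adult
operative hospitalizations with up to 40 diagnosis slots and survey
weights — under a known generative model, so every pipeline stage has
ground truth:

* **Demographics**: age ~ truncated normal (mean 55, sd 20, 18–105,
  integerized); P(male) = 0.39.
* **Deficit prevalences** (marginal targets): cancer 4.3%, weight loss
  1.1%, poor appetite 0.2%, kidney failure 3.9%, CHF 10.7%, shortness of
  breath 2.0%, cognitive decline 2.8%; functional status
  93.8/4.9/1.3%. Each deficit's probability climbs with age on the logit
  scale (slopes 0.03–0.09 per year, steepest for the geriatric syndromes),
  with the intercept solved so the empirical marginal hits its target;
  zero slopes give fully independent deficits for clean unit tests.
  Moderate- and mild-tier cancer codes are additionally emitted at 2.0%
  and 2.5% without any mortality contribution, so cancer-definition
  selection has a known answer (severe).
* **Mortality**: `P(death) = expit(α + S/c)` with S the true score from
  the configured weight table, default `c = 8` (≈0.125 log-odds per
  point, matching the gradient the published projected-mortality
  geometry implies), and α solved by Brent's method to hit the target
  overall mortality (default 2.4%, within the 2.1–2.5% band of the
  emulated populations).
* **Coding**: one mapped code per present deficit (drawn uniformly from
  the parameter's patterns), Poisson(3) distractor codes from a fixed
  20-code unmapped pool, slots capped at 40. Of simulated deaths, 20%
  are flagged only by a Z51.5 comfort-care code with a non-died
  disposition and 5% of the rest carry both triggers, exercising both
  arms of the composite mortality definition.
* **Dressing**: survey weights ~ U(4.5, 5.5) (a 20%-sample-like scale),
  200 hospital cluster labels, elective/length-of-stay/charges drawn per
  true category (gamma models with category means 4.4–8.8 days and
  $89k–$151k — decorative, not validated against real data), and
  missingness injected at 1–4% per optional field (sex 2%), below the 5%
  the emulated data report.

What the generator deliberately does **not** emulate: survey
strata/PSU design beyond cluster labels, code-assignment error
(sensitivity/specificity of coding), correlation between deficits beyond
their common age dependence, within-hospital outcome correlation, and
secular trends. Passing tests therefore demonstrate internal consistency
and statistical correctness of the pipeline under the stated model, not
instrument performance on real claims.

## Numerical and design choices

* Ratios with zero denominators are NaN throughout; they are never
  silently 0.
* `round` is numpy's round-half-to-even; integer points are stable
  because fitted values land on .5 boundaries with probability ~0.
* The intercept solve brackets α in [−40, 15] and converges to 1e-8;
  boundary targets (0 or 1) fail loudly.
* Bootstrap resample counts and seeds are explicit arguments with logged
  defaults; all generator randomness flows from one `numpy` Generator.
* Problem sizes used by the test suite — 2×10⁵ records for
  weight-table recovery, 10⁵ for end-to-end consistency, 5×10⁴ for
  distributional fidelity — were chosen as the smallest sizes at which
  the corresponding statistical checks are well powered (a
  pre-registered power analysis of the ±1-point recovery tolerance drove
  the 2×10⁵ figure; the rare poor-appetite parameter, at 0.2% prevalence
  and 1 point, is the one cell that can legitimately miss ±1 at this
  size, and the 95%-of-cells criterion absorbs it).

## Known limitations

* The packaged code map is a reconstruction (above): real-data scores
  require the licensed code list transcribed into the map format.
* Sandwich variances treat weights as relative frequencies; design-based
  (stratified Taylor) variances are not implemented.
* ICD-10-PCS operative-procedure classification is out of scope: the
  operative flag is consumed as a precomputed boolean, as discharge
  datasets provide.
* No cross-hospitalization linkage, readmission logic, ICD-9 mapping or
  comparator indices (HFRS, VA-FI, CFI); external scores can be compared
  via `convergent_validity`.
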