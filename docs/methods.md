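# Methods

## The screening procedure

The estimand for each concomitant drug class is the difference in
glycemic-control success probability between exposed patients and
covariate-comparable unexposed patients.

**Outcome.** A patient is a success iff the arithmetic mean of their HbA1c
values inside the closed window [90, 365] days after the DM-2 diagnosis is
strictly below 6.5%. The boundary is strict: a window mean of exactly 6.5
is a failure. Patients with no in-window HbA1c have an undefined outcome
and never reach analysis; their count is reported in `cohort.attrs`.

**Index date and exposure.** The index date is the first DM-2 diagnosis;
cohort entry additionally requires an antidiabetic purchase on or after it
(incident-user design). A patient counts as exposed to a concomitant class
if any purchase of it occurs on or before index + 365 days. Purchases
proxy use; no washout or coverage model is applied. A stricter
post-diagnosis-only window is available in `CohortCriteria`.

**Covariates.** Weight and BMI enter as the five summaries
(mean/median/max/min/sample SD) of all pre-index measurements; SD uses the
n−1 denominator and is 0 for a single measurement. Age is a single value
at the index date (its five summaries over one time point would collapse).
Smoking is ordinal: never = 0, past = 1, current = 2 — an exposure-burden
coding. Sex is deliberately not a matching feature: the matching feature
set is weight, age, BMI and smoking, twelve columns in all.

**Propensity and matching.** For each class, exposure is regressed on the
standardized features by maximum-likelihood logistic regression (IRLS with
step-halving; convergence at score max-norm < 1e-8, cap 100 iterations;
zero-variance columns dropped; rank-deficient designs rejected naming the
collinear columns; separation returns a flagged, unconverged model). Each
exposed patient is paired with the unexposed patient of closest propensity
score, with replacement and no caliper by default (a caliper is
configurable). Ties resolve to the smallest control id, which makes the
matching deterministic and invariant to presentation order. Note the
propensity model predicts *exposure*, the quantity propensity-score
methodology requires, not the outcome.

**Balance rules.** A matched control contributes one copy per pair
("expanded" controls) both to the KS balance tests and to the outcome
table — with replacement the two arms have equal pair counts but unequal
unique patients, so reuse must be accounted for somewhere, and expansion
keeps the 2×2 margins honest about the effective comparison actually made.
A class is excluded when the resampling rate 1 − unique/pairs exceeds
0.20, or when any feature's post-match two-sample KS p-value falls below
0.001 (small p = arms still differ on that covariate). KS on tied discrete
features (smoking) is computed on the data as-is, which can only make the
test conservative. The default threshold is 0.001; the rule's direction
follows conventional balance-diagnostic semantics. Excluded classes are
still tabulated and reported for audit, flagged, and omitted from the
findings section.

**Testing and multiplicity.** The per-class test is the uncorrected
Pearson χ² on the 2×2 success/failure table (a Yates-corrected variant is
exposed as a flag but is not the default; the uncorrected statistic is
what the matched-comparison reconstruction reproduces, 16.79 on the table
rebuilt from 1356/1221 at 61%/53%). Expanded pairs are treated as
independent. The Bonferroni multiplier is the number of classes tested
(post-eligibility, pre-exclusion). Results sort by (raw p, class code) so
reports are platform-stable and byte-identical across reruns.

**KS p-value.** The asymptotic Kolmogorov survival function
Q(λ) = 2·Σ_{k≥1} (−1)^{k−1} exp(−2k²λ²), truncated at 100 terms
(tolerance 1e-10), evaluated at λ = √(n_x n_y/(n_x+n_y))·D. Exact
small-sample p-values are out of scope: screening only ever tests groups
of ≥ 200.

## The synthetic-EHR generator

The generator emulates the study's raw material with known truth so every
stage is verifiable without real records.

*Population.* All simulated patients are incident DM-2 diabetics: 48%
male; age ~ N(62, 11²) clipped to [25, 90]; smoking
never/past/current = 0.55/0.25/0.20; weight N(84, 12²) for men and
N(72, 13²) for women; BMI N(29.5, 4.5²). Diagnosis dates are uniform on
days [365, 1500] of an abstract integer-day axis (day 0 = study start; no
calendar drift is modeled), leaving pre-index history for 1–6 weight/BMI
measurements per patient. Every patient gets an antidiabetic purchase 0–60
days post-diagnosis (biguanide 75%, sulfonylurea 15%, DPP-4 7%, insulin
3%).

*Drug classes.* 73 concomitant classes by default: the planted class
(`ALPHA1`), 67 "common" classes with exposure prevalence uniform in
[0.06, 0.13], and 5 "straddler" classes whose expected purchaser counts
are drawn uniformly in [0.7, 1.3] × 200 — scale-free in n, so the
eligibility filter is genuinely exercised at any study size (eligible-class
counts land in 68–73). Non-planted uptake is independent of covariates and
outcome: true nulls.

*Planted uptake (confounding by indication).* Uptake follows a logistic
model with log-odds confounding_strength·z_age + 0.5·confounding_strength·z_bmi,
a −4.5 shift for women, and an intercept calibrated by root-finding on the
realized covariates so the prevalence hits its target (default 0.075 of
patients). Purchasers draw a component from the configured mix, default
alfuzosin 27% / doxazosin 18% / terazosin 6% / tamsulosin 49%. A BPH
diagnosis code is emitted for 95% of planted purchasers and ~20% of
unexposed men over 60, so diagnosed-but-untreated comparisons can be
constructed.

*Success.* Success probability is logistic in z_age (−0.10), z_bmi
(−0.06) and smoking level (−0.05), plus planted_effect (default 0.327 =
logit(0.61) − logit(0.53)) for planted purchasers; the intercept is
calibrated so the marginal success rate is 0.54. Covariate effects are
deliberately mild — in the emulated population glycemic control varies
only gently with demographics — which places the planted class's matched
control arm near 53% and its treated arm near 61% at the defaults
(measured means over 50 replicates: 0.615 / 0.525). At the default
confounding strength the raw bias on the planted class is ≈ −1 to −2
percentage points; the property test that demonstrates visible raw bias
uses confounding_strength = 3, where the bias reaches ≈ −4.5 points
(> 3 Monte-Carlo SEs at n = 50,000). Sex has no direct success effect, so
its absence from the matching feature set introduces no residual bias.

*Labs.* The realized success label is expressed as HbA1c: in-window
values are drawn N(6.5 ∓ 0.8, 0.3²) (success/failure), rounded to 0.01,
plus one elevated baseline HbA1c at diagnosis. About 5% of patients draw
zero in-window labs (Poisson visits at 4/year over the 275-day window) and
are excluded by the cohort builder — outcome labeling recovers the
generative label for ≥ 99.9% of the rest. Determinism: one
`numpy.random.Generator` seeded from `SimConfig.seed`, all floats rounded
at generation, so a fixed seed yields byte-identical CSVs.

*What the generator does not emulate:* dosing, adherence, drug eras,
real code dictionaries, visit-process dependence on health state,
time-varying covariates, or correlated polypharmacy. Passing tests show
the pipeline recovers planted truth under clean confounding of the
modeled kind; they do not certify performance against real EHR artifacts
such as informative missingness.

## Study sizes used in validation

The replicated end-to-end checks run 50 screens each. The power study runs
at the reference scale of 29,540 patients (≈ 2,100 planted purchasers
after cohort attrition), where the planted class ranks first with
Bonferroni-adjusted p < 0.05 in ≈ 97% of replicates. The null-calibration
study (planted effect off, confounding on) runs at 10,000 patients — null
behaviour is scale-free because class eligibility straddles the cutoff by
construction — and requires the family-wise rate of adjusted-significant
findings to stay within binomial noise of α = 0.05, and the confounded
age imbalance to shrink after matching in ≥ 90% of replicates.

## Known limitations

- With-replacement matching induces dependence between pairs that the
  Pearson test ignores; at the default 20% reuse cap the inflation is
  modest. A pairs-respecting McNemar variant is available as a sensitivity
  analysis (`ScreenConfig(use_mcnemar=True)`) but is not the default.
- Single-feature KS exclusion at p < 0.001 over 12 features trips on
  ~1% of well-matched classes by chance; exclusion status is therefore
  reported alongside, not instead of, the test results.
- The Bonferroni multiplier counts tested classes only; classes failing
  the 200-patient eligibility filter are invisible to the correction.
- Propensity scores balance features only in expectation given the score;
  strongly sex-linked covariates (weight) can retain small residual
  imbalance in finite samples, occasionally excluding even a genuinely
  beneficial class.
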