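# glyscreen

Propensity-matched screening of concomitant drug classes for
glycemic-control benefit in EHR-style data.

## The problem

Newly diagnosed type-2 diabetics take many drugs besides their antidiabetic
medication. Some of those concomitant drugs may themselves help (or hinder)
glucose control, but their uptake is confounded by indication: for example,
alpha-1-adrenoceptor antagonists (alfuzosin, doxazosin, terazosin,
tamsulosin) are taken almost exclusively by older men with benign prostatic
hyperplasia, a demographic whose glycemic control differs from the cohort
at large. A naive comparison of purchasers versus non-purchasers is
therefore biased, and testing dozens of drug classes at once inflates the
false-discovery risk.

`glyscreen` implements the full screening pipeline for this setting:

1. **Cohort building** — patients enter at their first DM-2 diagnosis,
   require an antidiabetic purchase on/after it, and are labeled a
   *success* iff their mean HbA1c in days 90–365 post-diagnosis is
   strictly below 6.5%. Covariates (weight, BMI) are summarized by
   mean/median/max/min/SD over pre-index measurements; age and smoking
   complete the feature set.
2. **Exhaustive matched screen** — for every drug class with ≥ 200 exposed
   patients: fit an exposure-propensity logistic model
   e(x) = P(exposed | x) by maximum likelihood, pair each exposed patient
   with the unexposed patient of closest propensity score (1:1 nearest
   neighbor **with replacement**), and compare success rates in a 2×2
   table with the uncorrected Pearson χ² test (df = 1).
3. **Balance-based exclusion** — a class is excluded when the control
   resampling rate 1 − (unique controls)/(pairs) exceeds 20%, or any
   matching feature's two-sample Kolmogorov–Smirnov test has p < 0.001
   after matching.
4. **Multiplicity control** — raw p-values are Bonferroni-corrected by the
   number of classes tested (p̃ = min(1, m·p)); the top-5 findings are
   reported.

All statistics (Pearson χ², two-sample KS with the asymptotic Kolmogorov
p-value, Bonferroni, logistic regression by IRLS) are implemented from
their defining formulas in `glyscreen.stats_core` and cross-checked against
scipy/statsmodels in the test suite.

Because real claims-level EHR data cannot be redistributed, the package
ships a synthetic-EHR generator (`glyscreen.synthetic_ehr`) that emulates
the study conditions with known ground truth: ~73 concomitant drug classes,
54% marginal success, one planted beneficial class with confounded
older-male uptake and component mix 27/18/6/49
(alfuzosin/doxazosin/terazosin/tamsulosin), and purchaser counts that
straddle the 200-patient eligibility cutoff. Every pipeline stage is tested
against the generator's truth.

## Worked example

```python
from glyscreen import (SimConfig, generate_population, extract_cohort,
                       screen_all, top_findings)

pop = generate_population(SimConfig(n_patients=15000, seed=7))
cohort = extract_cohort(pop)
results = screen_all(cohort)
for r in top_findings(results, 5):
    print(r.drug_class, r.n_treated, f"{r.success_rate_treated:.3f}",
          f"{r.success_rate_control:.3f}", f"{r.chi2_statistic:.2f}",
          f"{r.p_bonferroni:.2e}")
```

prints (seed 7):

```
ALPHA1 1117 0.595 0.512 15.67 5.36e-03
C037   1382 0.530 0.576  5.99 1.00e+00
C038    909 0.513 0.565  5.10 1.00e+00
C010   1718 0.559 0.524  4.22 1.00e+00
C059   1394 0.531 0.565  3.34 1.00e+00
```

Only the planted class `ALPHA1` survives the Bonferroni bar: its matched
arms show 59.5% vs 51.2% success (χ² = 15.67, adjusted p ≈ 0.005), while
every true-null class lands at an adjusted p of 1. The scripts in
`examples/` walk through each capability (simulation, fixed two-group
comparison, the full screen, balance diagnostics) and print what the
numbers mean.

A thin CLI wraps the same library:

```bash
glyscreen simulate --n 10000 --seed 1 --out data/
glyscreen run --data data/ --out report.json
glyscreen compare --table 151,102,119,127
```

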