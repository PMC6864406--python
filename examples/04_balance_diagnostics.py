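"""Why matching is needed, and how balance is judged.

Shows, for the confounded planted class: the biased raw comparison, the
propensity-score separation before matching, and the per-feature KS balance
diagnostics after matching with replacement.
"""

from glyscreen import (
    SimConfig,
    assess_balance,
    extract_cohort,
    generate_population,
    match_with_replacement,
    propensity_scores,
)
from glyscreen.matching_engine import feature_ks

pop = generate_population(SimConfig(n_patients=10000, seed=11))
cohort = extract_cohort(pop)
exposed = cohort["rx_ALPHA1"] == 1

raw_t = cohort.loc[exposed, "outcome"].mean()
raw_c = cohort.loc[~exposed, "outcome"].mean()
print(f"raw success rates: exposed {raw_t:.3f} vs unexposed {raw_c:.3f}")

scores = propensity_scores(cohort, "ALPHA1")
print(
    f"mean propensity score: exposed {scores[exposed].mean():.3f} vs "
    f"unexposed {scores[~exposed].mean():.3f}  (confounded uptake)"
)

matched = match_with_replacement(scores[exposed], scores[~exposed], drug_class="ALPHA1")
print(
    f"matched {matched.n_treated} treated to {matched.n_control_unique} unique "
    f"controls; resampling rate {matched.resampling_rate:.1%}"
)

report = assess_balance(matched, cohort)
pre = feature_ks(
    cohort, cohort.index[exposed], cohort.index[~exposed], ("age", "weight_mean", "bmi_mean")
)
print(f"\n{'feature':<12} {'KS pre':>8} {'KS post':>8} {'p post':>10}")
for feat in ("age", "weight_mean", "bmi_mean"):
    d_post, p_post = report.ks[feat]
    print(f"{feat:<12} {pre[feat][0]:>8.3f} {d_post:>8.3f} {p_post:>10.3g}")
print(f"\nverdict: {report.verdict}  {report.reasons or ''}")
print(
    "\nMatching collapses the covariate gaps (KS statistics shrink by an order\n"
    "of magnitude); a class is excluded when reuse exceeds 20% or any feature\n"
    "stays imbalanced at KS p < 0.001."
)
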