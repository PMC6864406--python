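"""The full exhaustive screen on a synthetic population.

Generates a mid-sized population, builds the cohort, screens every eligible
concomitant drug class with propensity matching, and prints the top
findings with Bonferroni-adjusted p-values.
"""

from glyscreen import (
    ScreenConfig,
    SimConfig,
    extract_cohort,
    generate_population,
    screen_all,
    top_findings,
)

pop = generate_population(SimConfig(n_patients=15000, seed=7))
cohort = extract_cohort(pop)
print(
    f"cohort: {len(cohort)} analyzable patients, "
    f"success rate {cohort['outcome'].mean():.3f}"
)

config = ScreenConfig(top_k=5)
results = screen_all(cohort, config)
print(f"tested {len(results)} drug classes (Bonferroni multiplier {len(results)})\n")

print(f"{'class':<8} {'n':>5} {'succ_t':>7} {'succ_c':>7} {'chi2':>7} {'p_bonf':>9} excl")
for r in top_findings(results, config.top_k):
    print(
        f"{r.drug_class:<8} {r.n_treated:>5} {r.success_rate_treated:>7.3f} "
        f"{r.success_rate_control:>7.3f} {r.chi2_statistic:>7.2f} "
        f"{r.p_bonferroni:>9.2e} {r.excluded}"
    )

planted = next(r for r in results if r.drug_class == "ALPHA1")
print(
    f"\nplanted class ALPHA1: matched success {planted.success_rate_treated:.1%} "
    f"vs {planted.success_rate_control:.1%}, resampling rate "
    f"{planted.balance.resampling_rate:.1%}"
)
print(
    "\nOnly the planted alpha-blocker-like class carries a true benefit; every\n"
    "other class is a true null, so with calibrated error control it alone\n"
    "should survive the Bonferroni bar."
)
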