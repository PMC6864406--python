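"""Single pre-specified two-cohort comparison.

Reproduces the style of contingency analysis used for diabetics with
untreated benign prostatic hyperplasia (253 patients, 151 successes) versus
diabetics without the diagnosis (246 patients, 119 successes): build the
2x2 success/failure table and run the uncorrected Pearson chi-squared test.
"""

from glyscreen import compare_fixed_groups

group_bph_untreated = [1] * 151 + [0] * 102
group_no_bph = [1] * 119 + [0] * 127

r = compare_fixed_groups(group_bph_untreated, group_no_bph, label="BPH-untreated vs no-BPH")

print(f"table (a,b,c,d): ({r.table.a}, {r.table.b}, {r.table.c}, {r.table.d})")
print(
    f"success rates: {r.success_rate_treated:.1%} (BPH untreated) vs "
    f"{r.success_rate_control:.1%} (no BPH)"
)
print(f"Pearson chi2 = {r.chi2_statistic:.3f}, p = {r.p_raw:.4f}")
print(
    "\nRounded to whole percent the rates are 60% vs 48%. A single\n"
    "pre-specified comparison gets no multiplicity correction."
)
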