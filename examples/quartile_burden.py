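"""Polygenic risk-allele burden: quartile odds ratios and the trend test.

Reproduces the quartile comparison from published 2x4 counts (reference
population vs a 51-member cancer-free cohort, stratified by quartiles of
the per-individual risk-allele total) and then runs the same machinery on
raw simulated totals.
"""

import numpy as np

from cffvar.burden import quartile_bins, quartile_table, quartile_table_from_counts
from cffvar.simulate import gen_burden_scenario

# Prostate-cancer panel: reference counts per quartile, cohort counts per quartile.
summary = quartile_table_from_counts([91, 64, 86, 53], [10, 10, 10, 21])
print("From printed counts (prostate panel):")
frame = summary.to_frame()
for _, row in frame.iterrows():
    ci = "" if np.isnan(row["ci_low"]) else f"  95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}"
    print(f"  {row['risk_alleles']:>3}  ref {row['reference_n']:>3}  cohort {row['cohort_n']:>2}  "
          f"OR {row['or']:.2f}{ci}")
print(f"  trend p = {summary.trend_p:.4f}")
print("Quartile 4 members carry ~3.6x the odds of being in the cohort; the")
print("rising trend is significant at p < 0.01.\n")

# The same analysis from raw totals: a doubling-odds gradient planted by the
# generator (membership odds double per quartile, true slope ln 2 = 0.693).
ref_totals, cohort_totals = gen_burden_scenario([1, 2, 4, 8], n_ref=4000, n_cohort=1000, seed=11)
bins = quartile_bins(ref_totals)
summary = quartile_table(ref_totals, cohort_totals, bins)
print(f"Simulated doubling-odds scenario: cutpoints {bins}")
print(f"  per-quartile ORs: {[round(v, 2) for v in summary.odds_ratios]}")
print(f"  trend slope {summary.trend_slope:.3f} (truth ln 2 = {np.log(2):.3f}), p = {summary.trend_p:.2e}")
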