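"""Per-SNP risk-allele frequency comparison against a large reference.

Simulates a 51-member cohort genotyped at a retained risk-SNP panel, builds
a gnomAD-style (allele frequency, allele number) reference table, and runs
the scan: per-SNP odds ratios with Wald CIs, nominal flags at p < 0.05 and
a Bonferroni-adjusted significance level.
"""

import numpy as np
import pandas as pd

from cffvar.association import allele_scan
from cffvar.model import RiskSNP
from cffvar.simulate import gen_cohort

rng = np.random.default_rng(12)
n_snps = 106
freqs = rng.uniform(0.1, 0.9, n_snps)
snps = [RiskSNP(rsid=f"rs{j}", cancer_type="BC", risk_allele="A", maf=float(freqs[j]))
        for j in range(n_snps)]
cohort, _ = gen_cohort(51, freqs, seed=13, variant_keys=[s.rsid for s in snps])
reference = pd.DataFrame({"rsid": [s.rsid for s in snps], "af": freqs, "an": 129_206})

table = allele_scan(cohort, reference, snps)
nominal = table[table["nominal"]]
print(f"{len(table)} SNPs scanned; Bonferroni level "
      f"{table.attrs['bonferroni_level_display']} (0.05/{n_snps})")
print(f"{len(nominal)} SNPs nominally significant at p < 0.05 "
      f"(~5% expected under the null):")
print(nominal[["rsid", "freq_reference", "freq_cohort", "or", "ci_low", "ci_high", "p"]]
      .round(4).to_string(index=False))
print(f"Bonferroni-significant SNPs: {int(table['bonferroni_significant'].sum())} — "
      "with a 51-member cohort drawn from the reference itself, none is expected.")
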