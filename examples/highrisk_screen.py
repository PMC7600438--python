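"""High-risk gene panel screen with ClinVar significance.

Plants a handful of rare missense variants in the default high-risk panel
(BRCA1/2, APC, MLH1, MSH2, MSH6, MUTYH, PMS2, HOXB13), runs the screen,
and computes the reference-side probability of carrying a ClinVar
pathogenic / likely-pathogenic variant per gene.
"""

import numpy as np

from cffvar.highrisk import DEFAULT_PANEL, reference_pathogenic_probability, screen_high_risk
from cffvar.model import SiteCounts
from cffvar.simulate import gen_annotated_variants

variants, _ = gen_annotated_variants(4, {"all_pass": 4}, seed=20,
                                     genes=["BRCA2", "APC", "MSH6", "MUTYH"])
variants[3].clinvar = "likely_pathogenic"  # the MUTYH-style hit
variants[1].rsid = None  # a variant absent from dbSNP
report = screen_high_risk(variants)
print(report[["gene", "snp_id", "prevalence", "cadd", "conservation_votes",
              "prediction_votes", "clinvar", "caveat"]].to_string(index=False))

# Reference side: pathogenic carrier probability per gene from AC/Hom/AN.
rng = np.random.default_rng(21)
sites, clinvar, genes = [], {}, {}
for i in range(50):
    gene = DEFAULT_PANEL[i % 4]
    an = 66_740
    q = float(rng.uniform(1e-5, 5e-4))
    s = SiteCounts(("13", 32_000_000 + i, "A", "G"), ac=round(q * an / 2), hom=0, an=an)
    sites.append(s)
    genes[s.variant_key] = gene
    clinvar[s.variant_key] = "pathogenic" if rng.random() < 0.2 else "benign"

print("\nreference pathogenic-carrier probability per gene:")
for gene in DEFAULT_PANEL[:4]:
    row = reference_pathogenic_probability(sites, clinvar, genes, gene)
    print(f"  {gene:6s} {row['total_variants']:3d} variants, "
          f"{row['pathogenic_variants']} pathogenic -> P = {row['p_reference_pct']}")
print("Genes with no qualifying cohort variant appear as 'Not found'; a gene")
print("with zero pathogenic reference variants has carrier probability 0.")
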