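# cffvar

Germline risk-allele and rare-variant carrier analysis for cancer-free
cohorts.

## The problem

Familial clustering and high-penetrance predisposition genes show that some
families carry an excess genetic risk of cancer. The mirror-image question —
whether families with no cancer history are genetically *protected* — can be
asked by sequencing elderly cancer-free index individuals and comparing
their germline against population references. `cffvar` implements that
comparison as a reusable, tested pipeline for three kinds of evidence:

1. **Common low-risk alleles.** GWAS risk SNPs for breast, colorectal and
   prostate cancer are filtered (specified risk allele and MAF, MAF outside
   (0.45, 0.55), published OR ≥ 1.04, no subtype-only associations, present
   in the genotype reference, LD-pruned at r² > 0.8), then compared per SNP
   between cohort and reference as allele-count odds ratios, and in
   aggregate as per-individual risk-allele totals binned by reference
   quartiles with a logistic trend test.
2. **Rare variants in candidate predisposition genes.** A conjunctive
   prioritization cascade (MAF < 0.1% in every reference source, scaled
   CADD > 10, ≥ 2/3 conservation votes from GERP/PhastCons/PhyloP, a strict
   majority of ten deleteriousness predictors, gene-intolerance screening)
   selects potentially pathogenic variants; carrier probabilities are then
   compared between cohort and reference.
3. **High-risk genes.** Rare missense/LoF variants in BRCA1/2, APC, MLH1,
   MSH2, MSH6, MUTYH, PMS2 and HOXB13 are listed with their annotations and
   ClinVar significance, alongside the reference probability of carrying a
   ClinVar pathogenic/likely-pathogenic variant per gene.

Because individual-level WGS of such cohorts is protected, the package
ships generators (`cffvar.simulate`) that emulate every input — HWE
genotypes, consistent AC/Hom/AN site counts, annotation tables with
controllable pass/fail composition — so every stage is testable end to end.

## The statistics at the core

For a site with alternate-allele count $AC_i$, homozygote count $Hom_i$ and
allele number $AN_i$, the fraction of individuals carrying at least one
allele is

$$q_i = \frac{AC_i - Hom_i}{AN_i/2},$$

and over $k$ qualifying variants, assuming independent sites,

$$P = 1 - \prod_{i=1}^{k}(1 - q_i)$$

is the probability that one individual carries at least one of them. Cohort
and reference probabilities compare as

$$OR = \frac{P_{\mathrm{cohort}}(1 - P_{\mathrm{ref}})}{(1 - P_{\mathrm{cohort}})\,P_{\mathrm{ref}}},$$

with a 95% CI from a bias-corrected and accelerated (BCa) bootstrap of the
cohort's per-individual carrier indicators (10,000 resamples, reference
held fixed; replicates with carrier fraction 0 or 1 map to OR 0/∞ at the
quantile extremes, which is how a zero lower bound arises). Allele-level
and quartile odds ratios are cross-product ratios with Wald inference —
identical to a binary-covariate logistic fit, which the test suite checks
by IRLS to six decimals. The quartile trend test is a logistic regression
of cohort membership on the quartile index 1–4 as a continuous covariate.

## Worked example

Quartile burden analysis from a published-style 2×4 count table (reference
individuals vs a 51-member cohort per risk-allele quartile):

```sh
python examples/quartile_burden.py
```

```
From printed counts (prostate panel):
   Q1  ref  91  cohort 10  OR 1.00
   Q2  ref  64  cohort 10  OR 1.42  95% CI 0.56-3.61
   Q3  ref  86  cohort 10  OR 1.06  95% CI 0.42-2.67
   Q4  ref  53  cohort 21  OR 3.61  95% CI 1.58-8.23
  trend p = 0.0055
```

Each OR compares that quartile's cohort:reference split with quartile 1;
members of the top prostate-cancer quartile have 3.6× the odds of being in
the cohort, and the trend over quartiles is significant at p = 0.0055.

Carrier probability with a BCa interval:

```sh
python examples/carrier_bootstrap.py
```

```
reference: 15 qualifying variants, per-site carrier frequencies 0.0032..0.0400
P(reference individual carries >= 1 variant) = 0.317
cohort: 17 of 51 individuals carry -> P = 0.333
OR = 1.08, BCa 95% CI (0.52, 1.77)
```

The cohort was simulated from the reference frequencies, so the interval
covers OR = 1. The other `examples/*.py` scripts demonstrate SNP selection
and LD pruning, the per-SNP allele scan, the prioritization cascade and the
high-risk screen, one capability each.

The same stages are available as a thin CLI over a shared workspace:

```sh
cffvar --seed 1 --workspace ws simulate   # generate the synthetic scenario
cffvar --seed 1 --workspace ws all        # qc, select-snps, allele-scan,
                                          # burden, prioritize, carrier, highrisk
```

Every report is TSV with a header echoing the configuration hash and seed;
two runs with the same config and seed are byte-identical.

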