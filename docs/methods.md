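# Methods

This note records the models, thresholds, numerical conventions and design
choices behind `cffvar`, and what the synthetic-data generators do and do
not emulate.

## Study design being modelled

The pipeline targets a case-reference design in which the "cases" are 51
elderly individuals from families with no cancer history and the references
are public aggregates: a large exome/genome reference for allele
frequencies and site counts (tens of thousands of non-Finnish European
individuals), and a 294-individual genotype-level reference for
quartile binning and LD. All coordinates are 1-based, VCF-style, and every
join is on `(chrom, pos, ref, alt)`.

## Quality control (`cffvar.qc`)

* A genotype call backed by fewer than `min_depth = 5` reads is set
  missing; a variant whose QUAL is not *strictly* above `min_qual = 20` is
  dropped. The strict/non-strict readings are deliberate: "minimum of 5"
  is ≥ 5, "higher than 20" is > 20.
* Site-level analyses keep positions with ≥ 10 reads in ≥ 90% of samples
  (both bounds inclusive; 46/51 ≈ 0.902 is in, 45/51 ≈ 0.882 is out).
* Relatedness is screened by pairwise dosage concordance — the fraction of
  co-called variants with identical dosage. No statistic or threshold is
  canonical for this design, so plain concordance with a configurable flag
  threshold (default 0.9) was chosen for transparency; flagged pairs are
  reported, never removed automatically. Two unrelated individuals at
  allele frequency f = 0.5 concord at Σ P(g)² = 0.375, so 0.9 flags only
  duplicates and first-degree relatives.

## Risk-SNP selection (`cffvar.snp_selection`)

Six exclusion criteria, applied in order with the first match recorded:
unspecified risk allele; unspecified MAF or MAF strictly inside
(0.45, 0.55) (the open interval is a documented reading of "between" — a
MAF of exactly 0.45 is retained; bounds configurable); published OR below
1.04; subtype-specific association only; absence from the genotype
reference; LD pruning. LD uses genotypic r² (squared Pearson correlation of
dosages over co-called individuals) computed from the reference genotypes,
not the 51-sample cohort, which estimates r² poorly. Linked clusters are
connected components of the r² > 0.8 graph (strictly greater; same
chromosome only); exactly one SNP per cluster survives — the one with
largest |ln OR|, ties to the smallest rsID — making the output invariant to
input order. Retaining the largest effect is this package's convention;
sources rarely state which SNP of a linked pair they kept.

## Allele-frequency comparison (`cffvar.association`)

Each SNP is an allele-level 2×2 table: cohort risk/other allele counts
against reference counts reconstructed as `round(AF·AN)` and
`AN − round(AF·AN)` (reference exports publish AF and AN, not risk-allele
counts keyed to GWAS risk alleles). The OR is the cross-product ratio with
`SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d)` and Wald CI/p — exactly the
binary-covariate logistic estimate, chosen over likelihood-ratio inference
because it is closed-form and matches common statistical-package defaults.
No continuity correction is applied; a zero cell yields an undefined OR
with a flagged record. Multiplicity is handled by a Bonferroni-adjusted
level α/m, reported at full precision and rounded to 4 decimals for
display (0.05/106 → 0.0005, 0.05/81 → 0.0006).

## Quartile burden and trend (`cffvar.burden`)

Per-individual burden is the unweighted sum of risk-allele dosages
(weighted polygenic scores are out of scope). Missing dosages default to
expected-value imputation (2·MAF from the panel), with a drop option.
Quartile cutpoints are the reference 25th/50th/75th percentiles floored to
integers, with bins `≤c1`, `c1+1..c2`, `c2+1..c3`, `>c3` so ties fall in
the lower bin and printed bin labels read like "88–91". Per-quartile ORs
are cross-products against quartile 1 (fixed at 1.00). The trend test
codes the quartile index 1–4 as a single continuous covariate in a
maximum-likelihood logistic fit and reports the two-sided Wald p on the
slope; separation is flagged, not raised. Which trend statistic (Wald,
score or LR) published tables used is typically unstated; the Wald choice
here reproduces a published prostate-panel trend p of 0.0055 from its
printed counts, and the test suite asserts it only to ±0.002.

## Prioritization cascade (`cffvar.prioritize`)

Five stages over gene-list-restricted variants of one consequence class
(`non_synonymous` = missense; `lof` = stop gain/loss, splice site,
frameshift indel):

| stage | rule | boundary |
|---|---|---|
| rarity | MAF < 0.001 in *every* available source | strict <; absent source = rare |
| CADD | scaled score > 10 | strict > |
| conservation | ≥ 2 votes of GERP > 2.0, PhastCons > 0.3, PhyloP ≥ 3.0 | PhyloP inclusive |
| deleteriousness | deleterious calls > half of tools *with data* | 6/10 when all ten score |
| intolerance | recorded in the audit | blocks only with configured thresholds |

The stages combine conjunctively, so the surviving set is the intersection
of per-stage pass sets and is order-invariant (tested exhaustively on
small fixtures). LoF variants skip the conservation and deleteriousness
votes: missense predictors do not score truncating variants, and published
LoF counts could not have passed a ten-predictor majority. Missing
CADD/conservation annotations pass through by default ("not evaluated");
`strict_missing` turns them into failures. Intolerance thresholds are
never stated in the source material, hence the non-blocking default. The
shipped gene-list fixtures carry the *structure* of a large (~723-gene)
and a curated (~114-gene) predisposition list, not the actual memberships,
which live in external reviews.

## Carrier probabilities and the BCa bootstrap (`cffvar.carrier`)

Per-site reference carrier frequency `q = (AC − Hom)/(AN/2)`; aggregate
probability `P = 1 − Π(1 − q_i)` under site independence. The cohort-side
probability is the *observed* carrier fraction (any non-zero called dosage
across qualifying variants); applying the aggregation formula to cohort
counts instead is available as an option, since published tables do not
state which was used. The OR is
`P_c(1 − P_r) / ((1 − P_c) P_r)`.

The 95% CI resamples cohort individuals (the 0/1 indicator vector) with
replacement, holding the reference probability fixed: the reference is
~3 orders of magnitude larger, its sampling error is negligible, and a
zero lower bound is only producible by cohort resampling. The bootstrap
statistic is θ = ln OR; replicates with resampled carrier fraction 0 or 1
map to ∓∞ and stay in the replicate distribution at the quantile extremes
rather than being discarded. Bias correction
`z₀ = Φ⁻¹(#{θ* < θ̂}/B)` (strict inequality, Efron's convention);
acceleration from the jackknife third-moment formula
`a = Σ(θ̄₋ᵢ − θ₋ᵢ)³ / (6[Σ(θ̄₋ᵢ − θ₋ᵢ)²]^{3/2})`, computed on the θ scale
and falling back to the (monotone-equivalent) carrier-fraction scale when
a leave-one-out estimate hits the boundary. Quantiles are
inverse-empirical-CDF (type 1), so intervals are bit-reproducible for a
fixed mandatory seed. Degenerate inputs (all indicators equal, or all
replicates equal) collapse to the point estimate with a flag. Forcing
z₀ = a = 0 reduces the interval to the plain percentile method, which the
tests exploit. B defaults to 10,000; the null-coverage check in the test
suite uses B = 2,000 over 500 simulated 51-member cohorts and observes
~94.8% coverage of OR = 1 (95% nominal).

## High-risk screen (`cffvar.highrisk`)

The default panel is BRCA1, BRCA2, APC, MLH1, MSH2, MSH6, MUTYH, PMS2,
HOXB13. Cohort-side rows are rare (< 0.001 in a configurable frequency
source) missense/LoF variants with CADD, conservation and predictor votes
("k/n" when fewer than all tools have data) and ClinVar significance;
genes without hits appear as "Not found", variants without an rsID as
"No dbSNP". The frequency source is a parameter because published
high-risk tables list variants whose reference prevalence exceeds the
stated cut — the population the cut was applied to is ambiguous, and the
package exposes the choice rather than resolving it. Compound ClinVar
strings collapse to the most severe listed category for screening (the raw
string is kept for reports); the MUTYH-recessive and PMS2/HOXB13
status-under-discussion caveats are static report annotations, not logic.
The reference side restricts site counts to ClinVar
pathogenic/likely-pathogenic variants per gene and applies the carrier
aggregation; zero pathogenic variants give P = 0.

## Synthetic data (`cffvar.simulate`)

Generators are pure functions of (parameters, seed) and their outputs pass
the corresponding readers' validation by construction.

* Genotypes are Binomial(2, f) per site (Hardy–Weinberg), independent
  across sites. Site independence is deliberate: the carrier aggregation
  formula assumes it, so fixtures satisfy it; LD exists only where planted
  by copying a template dosage vector with per-individual flip noise
  (default flip probability 0.02 lands r² ≈ 0.96, safely above the 0.8
  pruning threshold).
* Reference site counts are tabulated from latent multinomial HWE genotype
  counts, so AC/Hom/AN invariants and carrier identities hold exactly.
* Annotation fixtures draw scores just inside/outside each cascade
  threshold to realise a requested profile (all-pass or fail exactly one
  stage), with ground truth retained for plant-recovery tests.
* Burden scenarios draw reference totals from a discretised normal
  (default mean 90, sd 5, sized like a ~100-SNP panel) and assign cohort
  members to quartiles with odds multipliers relative to the reference
  composition, so weights (1, 2, 4, 8) give a logistic trend slope of
  exactly ln 2 in expectation.
* Default scales mirror the study design: 51 cohort individuals, 294
  genotype-reference individuals, site counts on a 33,370-individual
  exome-reference scale. The generators make no attempt to mimic realistic
  site-frequency spectra, annotation correlations (CADD and conservation
  are drawn independently), population structure or sequencing-platform
  batch effects — so passing tests demonstrate the *machinery* is correct
  under the analysis's own assumptions, not that those assumptions hold in
  real cohorts.

## Problem sizes and runtime

The default CLI scenario (51 cohort × ~100 risk SNPs and ~116 rare
variants, 294 genotype-reference individuals, 33,370-individual site
counts, B = 10,000) runs in a few seconds on one CPU. The test suite's
statistical checks use 500 bootstrap-coverage simulations at B = 2,000,
10⁵-draw independence simulations, 100-variant cascade fixtures and
brute-force LD-pruning oracles on ≤ 8 SNPs; the whole suite completes in
well under a minute.

## Known limitations

* The published per-SNP tables and carrier probabilities that depend on
  actual gnomAD/ExAC payloads are not reproducible without those payloads;
  the package reproduces everything derivable from printed count tables
  and validates the rest against closed forms, simulations and independent
  implementations.
* Allele-level (per-chromosome) logistic comparison is assumed for the
  frequency scan; genotype-level regression would differ slightly.
* The carrier OR treats the reference probability as fixed; its (tiny)
  sampling error is ignored by design.
* Bootstrap resampling is over individuals only, not variants.
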