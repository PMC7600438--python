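"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes so
that all stages are testable without protected genotype data:

* Hardy–Weinberg genotypes at stated frequencies, independent across sites
  (the carrier-probability aggregation itself assumes independent sites, so
  fixtures satisfy it; LD exists only where explicitly planted);
* reference site-count (AC/Hom/AN) tables tabulated from latent simulated
  genotypes, so every row satisfies the count invariants by construction;
* annotation tables whose scores are drawn just inside or outside each
  cascade threshold to realise a requested pass/fail profile, with the
  ground truth retained;
* risk-SNP panels with one planted exemplar per exclusion criterion and LD
  blocks built by copying a template dosage vector with flip noise;
* quartile-burden scenarios with a controllable cohort-membership gradient.

Default scales mirror the study design: 51 cohort individuals, 294
reference individuals for quartile binning, and site counts on a
33,370-individual exome-reference scale.  All generators are pure functions
of their parameters and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    AnnotatedVariant,
    GenotypeMatrix,
    RiskSNP,
    SiteCounts,
    ValidationError,
    variant_key,
)
from .qc import SiteDepthTable

__all__ = [
    "gen_cohort",
    "gen_reference_sites",
    "gen_annotated_variants",
    "gen_risk_snp_panel",
    "gen_burden_scenario",
    "DEFAULT_COHORT_SIZE",
    "DEFAULT_QUARTILE_REFERENCE_SIZE",
    "DEFAULT_EXOME_REFERENCE_SIZE",
]

DEFAULT_COHORT_SIZE = 51
DEFAULT_QUARTILE_REFERENCE_SIZE = 294
DEFAULT_EXOME_REFERENCE_SIZE = 33_370


def _default_keys(n: int, chrom_count: int = 22):
    keys = []
    for i in range(n):
        chrom = str(i % chrom_count + 1)
        keys.append(variant_key(chrom, 10_000 + 100 * i, "A", "G"))
    return keys


def gen_cohort(
    n_individuals: int,
    site_freqs,
    seed: int,
    with_depth: bool = False,
    depth_mean: float = 42.0,
    low_depth_fraction: float = 0.0,
    n_low_qual: int = 0,
    variant_keys=None,
) -> tuple[GenotypeMatrix, SiteDepthTable | None]:
    """Simulate a cohort dosage matrix under Hardy–Weinberg equilibrium.

    Dosages are Binomial(2, f) independently per site.  With
    ``with_depth=True`` a per-call read-depth table is drawn (Poisson with
    mean ``depth_mean``, matching deep whole-genome coverage) in which a
    fraction ``low_depth_fraction`` of calls is replaced by depths in 0..4,
    and ``n_low_qual`` variants receive QUAL <= 20 — the planted failures
    the QC filters must find.
    """
    freqs = np.asarray(site_freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValidationError("site frequencies must lie in [0,1]")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, freqs, size=(n_individuals, len(freqs))).astype(float)
    ids = [f"CFF{i + 1:03d}" for i in range(n_individuals)]
    keys = list(variant_keys) if variant_keys is not None else _default_keys(len(freqs))
    matrix = GenotypeMatrix(ids, keys, dosages)
    depth_table = None
    if with_depth:
        depths = rng.poisson(depth_mean, size=(len(freqs), n_individuals)).astype(int)
        if low_depth_fraction > 0:
            low = rng.random(depths.shape) < low_depth_fraction
            depths[low] = rng.integers(0, 5, size=int(low.sum()))
        qual = rng.uniform(30.0, 60.0, size=len(freqs))
        if n_low_qual:
            low_idx = rng.choice(len(freqs), size=n_low_qual, replace=False)
            qual[low_idx] = rng.uniform(5.0, 20.0, size=n_low_qual)
        index = pd.Index([":".join(map(str, k)) for k in keys])
        depth_table = SiteDepthTable(
            depths=pd.DataFrame(depths, index=index, columns=ids),
            qual=pd.Series(qual, index=index, name="qual"),
        )
    return matrix, depth_table


def gen_reference_sites(
    n_individuals: int,
    site_freqs,
    seed: int,
    variant_keys=None,
    return_latent: bool = False,
):
    """Simulate a reference AC/Hom/AN table from latent HWE genotypes.

    Per site the genotype counts are Multinomial(n, [(1-f)^2, 2f(1-f), f^2]);
    AC = het + 2*hom, Hom = hom, AN = 2n, so every row satisfies the count
    invariants by construction and AC - Hom equals the simulated carrier
    count.  ``return_latent=True`` additionally returns the (het, hom)
    counts for identity checks.
    """
    freqs = np.asarray(site_freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValidationError("site frequencies must lie in [0,1]")
    rng = np.random.default_rng(seed)
    keys = list(variant_keys) if variant_keys is not None else _default_keys(len(freqs))
    sites, latent = [], []
    for f, key in zip(freqs, keys):
        probs = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        n_ref, n_het, n_hom = rng.multinomial(n_individuals, probs)
        sites.append(SiteCounts(variant_key=key, ac=int(n_het + 2 * n_hom), hom=int(n_hom), an=2 * n_individuals))
        latent.append((int(n_het), int(n_hom)))
    if return_latent:
        return sites, latent
    return sites


# ---------------------------------------------------------------------------
# annotated variants with planted cascade profiles

PROFILES = ("all_pass", "fail_maf", "fail_cadd", "fail_conservation", "fail_deleteriousness")


def _passing_scores(rng):
    return {
        "mafs": {
            "thousand_genomes": float(rng.uniform(0, 9e-4)),
            "exac_nfe_nontcga": float(rng.uniform(0, 9e-4)),
            "local": float(rng.uniform(0, 9e-4)),
        },
        "cadd": float(rng.uniform(10.5, 35.0)),
        "gerp": float(rng.uniform(2.1, 6.0)),
        "phastcons": float(rng.uniform(0.31, 1.0)),
        "phylop": float(rng.uniform(3.0, 9.0)),
        "n_deleterious": int(rng.integers(6, 11)),
    }


def gen_annotated_variants(
    n: int,
    stage_fail_mix: dict,
    seed: int,
    genes=None,
    consequence: str = "missense",
    start_pos: int = 5_000,
) -> tuple[list[AnnotatedVariant], list[str]]:
    """Generate annotated variants realising requested cascade profiles.

    ``stage_fail_mix`` maps profile names (:data:`PROFILES`) to counts that
    must sum to ``n``.  Scores are drawn just inside or outside each
    threshold: MAF around 1e-3, CADD around 10, conservation around the
    2-of-3 vote, predictor calls around the strict majority.  Returns the
    variants together with the ground-truth profile per variant.  For
    loss-of-function consequences only ``all_pass``, ``fail_maf`` and
    ``fail_cadd`` are feasible (the vote stages do not apply).
    """
    counts = dict(stage_fail_mix)
    unknown = set(counts) - set(PROFILES)
    if unknown:
        raise ValidationError(f"unknown profiles: {sorted(unknown)}")
    if sum(counts.values()) != n:
        raise ValidationError(f"profile counts sum to {sum(counts.values())}, expected {n}")
    is_lof = consequence != "missense"
    if is_lof and (counts.get("fail_conservation") or counts.get("fail_deleteriousness")):
        raise ValidationError("vote-stage failure profiles are infeasible for LoF variants")
    rng = np.random.default_rng(seed)
    profile_list: list[str] = []
    for name in PROFILES:
        profile_list += [name] * counts.get(name, 0)
    variants = []
    for i, profile in enumerate(profile_list):
        s = _passing_scores(rng)
        if profile == "fail_maf":
            source = ("thousand_genomes", "exac_nfe_nontcga", "local")[int(rng.integers(3))]
            s["mafs"][source] = float(rng.uniform(1.1e-3, 1e-2))
        elif profile == "fail_cadd":
            s["cadd"] = float(rng.uniform(0.0, 10.0))
        elif profile == "fail_conservation":
            # at most one vote: GERP stays positive, the other two fail
            s["phastcons"] = float(rng.uniform(0.0, 0.29))
            s["phylop"] = float(rng.uniform(0.0, 2.9))
        elif profile == "fail_deleteriousness":
            s["n_deleterious"] = int(rng.integers(0, 6))
        calls = {}
        deleterious_tools = rng.permutation(10)[: s["n_deleterious"]]
        from .model import PREDICTOR_TOOLS

        for t_idx, tool in enumerate(PREDICTOR_TOOLS):
            calls[tool] = "deleterious" if t_idx in deleterious_tools else "tolerated"
        gene = genes[i % len(genes)] if genes else f"GENE{i % max(n // 2, 1):04d}"
        variants.append(
            AnnotatedVariant(
                chrom=str(i % 22 + 1),
                pos=start_pos + 37 * i,
                ref_allele="C",
                alt_allele="T",
                gene=gene,
                consequence=consequence,
                maf_by_source=s["mafs"],
                cadd_phred=s["cadd"],
                gerp=None if is_lof else s["gerp"],
                phastcons=None if is_lof else s["phastcons"],
                phylop=None if is_lof else s["phylop"],
                predictor_calls={} if is_lof else calls,
                rsid=f"rs9{seed % 1000:03d}{i:04d}",
            )
        )
    return variants, profile_list


# ---------------------------------------------------------------------------
# risk-SNP panels with planted exclusions and LD blocks

def gen_risk_snp_panel(
    n_clean: int,
    exclusion_mix: dict | None,
    seed: int,
    n_reference: int = DEFAULT_QUARTILE_REFERENCE_SIZE,
    cancer_type: str = "BC",
    flip_prob_linked: float = 0.02,
) -> tuple[list[RiskSNP], GenotypeMatrix, dict]:
    """Risk-SNP list plus reference genotypes with planted LD blocks.

    ``n_clean`` SNPs pass every criterion.  ``exclusion_mix`` maps criterion
    numbers 1..6 to counts of planted offenders; a criterion-6 plant copies
    the dosage vector of a clean partner with per-individual flip noise
    (replacement probability ``flip_prob_linked``, which lands the pairwise
    r-squared near (1 - p)^2, well above 0.8 at the default).  Returns
    (snps, reference genotype matrix keyed by rsID, truth) where ``truth``
    maps each rsID to its expected exclusion reason (None = retained).
    """
    exclusion_mix = dict(exclusion_mix or {})
    unknown = set(exclusion_mix) - {1, 2, 3, 4, 5, 6}
    if unknown:
        raise ValidationError(f"unknown exclusion criteria: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    snps: list[RiskSNP] = []
    truth: dict = {}
    columns: dict = {}
    counter = 0

    def fresh_rsid():
        nonlocal counter
        counter += 1
        return f"rs{10_000 + counter}"

    clean_ids = []
    for _ in range(n_clean):
        rsid = fresh_rsid()
        maf = float(rng.uniform(0.05, 0.40))
        snps.append(
            RiskSNP(
                rsid=rsid,
                cancer_type=cancer_type,
                risk_allele=str(rng.choice(list("ACGT"))),
                maf=maf,
                or_published=float(rng.uniform(1.05, 1.50)),
                chrom=str(rng.integers(1, 23)),
                pos=int(rng.integers(1, 10**8)),
            )
        )
        columns[rsid] = rng.binomial(2, maf, size=n_reference).astype(float)
        truth[rsid] = None
        clean_ids.append(rsid)

    for reason, count in sorted(exclusion_mix.items()):
        for _ in range(count):
            rsid = fresh_rsid()
            maf = float(rng.uniform(0.05, 0.40))
            snp = RiskSNP(
                rsid=rsid,
                cancer_type=cancer_type,
                risk_allele=str(rng.choice(list("ACGT"))),
                maf=maf,
                or_published=float(rng.uniform(1.05, 1.50)),
                chrom=str(rng.integers(1, 23)),
                pos=int(rng.integers(1, 10**8)),
            )
            if reason == 1:
                snp.risk_allele = None
            elif reason == 2:
                snp.maf = float(rng.uniform(0.451, 0.549))
            elif reason == 3:
                snp.or_published = float(rng.uniform(1.001, 1.039))
            elif reason == 4:
                snp.subtype_specific = True
            elif reason == 5:
                snp.in_thousand_genomes = False
            elif reason == 6:
                if not clean_ids:
                    raise ValidationError("criterion-6 plant needs at least one clean SNP")
                partner = clean_ids[int(rng.integers(len(clean_ids)))]
                partner_snp = next(s for s in snps if s.rsid == partner)
                snp.chrom, snp.pos = partner_snp.chrom, (partner_snp.pos or 0) + 500
                snp.maf = partner_snp.maf
                # Weaker effect than the partner so the plant is the one pruned.
                snp.or_published = max(1.041, (partner_snp.or_published or 1.1) - 0.01)
                template = columns[partner]
                flip = rng.random(n_reference) < flip_prob_linked
                copied = template.copy()
                copied[flip] = rng.binomial(2, partner_snp.maf, size=int(flip.sum()))
                columns[rsid] = copied
            if reason != 6:
                columns[rsid] = rng.binomial(2, maf if snp.maf is None else snp.maf, size=n_reference).astype(float)
            snps.append(snp)
            truth[rsid] = reason
    order = [s.rsid for s in snps]
    dosages = np.column_stack([columns[r] for r in order])
    ids = [f"REF{i + 1:04d}" for i in range(n_reference)]
    reference = GenotypeMatrix(ids, order, dosages)
    return snps, reference, truth


# ---------------------------------------------------------------------------
# burden scenarios

def gen_burden_scenario(
    effect_profile,
    n_ref: int,
    n_cohort: int,
    seed: int,
    mean: float = 90.0,
    sd: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired reference / cohort risk-allele totals with a quartile gradient.

    Reference totals come from a discretised normal (defaults sized like a
    ~100-SNP panel).  ``effect_profile`` gives the four per-quartile
    cohort-membership odds multipliers relative to the reference: each
    cohort member draws a quartile with probability proportional to
    ``weight * reference_quartile_size``, then a total uniformly from the
    reference totals of that quartile.  The cohort:reference odds of
    quartile q vs q' are then exactly ``w_q / w_q'`` — weights (1, 2, 4, 8)
    are the doubling-odds scenario with logistic trend slope ln 2, and a
    flat profile has slope 0 regardless of tie-induced quartile imbalance.
    """
    weights = np.asarray(effect_profile, dtype=float)
    if weights.shape != (4,) or (weights < 0).any() or weights.sum() == 0:
        raise ValidationError("effect_profile must be 4 non-negative weights")
    rng = np.random.default_rng(seed)
    ref = np.round(rng.normal(mean, sd, size=n_ref)).clip(min=0).astype(int)
    from .burden import assign_quartiles, quartile_bins

    bins = quartile_bins(ref)
    quartile = assign_quartiles(ref, bins)
    pools = [ref[quartile == q] for q in (1, 2, 3, 4)]
    if any(len(p) == 0 for p in pools):
        raise ValidationError("a reference quartile is empty; increase n_ref")
    sized = weights * np.array([len(p) for p in pools], dtype=float)
    probs = sized / sized.sum()
    chosen = rng.choice(4, size=n_cohort, p=probs)
    cohort = np.array([pools[q][rng.integers(len(pools[q]))] for q in chosen])
    return ref.astype(float), cohort.astype(float)
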