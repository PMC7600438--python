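"""Selection of GWAS risk SNPs: six exclusion criteria plus greedy LD pruning.

A candidate SNP is removed if any of the following applies (each removal is
tagged with the first matching criterion):

1. the risk allele is unspecified;
2. the MAF is unspecified, or lies strictly between 0.45 and 0.55 (a SNP
   with MAF exactly 0.45 or 0.55 is retained; bounds configurable);
3. the published risk-allele odds ratio is below 1.04;
4. the association is subtype-specific (ER status / histology only);
5. the SNP is absent from the 1000-Genomes reference;
6. it is linked (pairwise r-squared > 0.8) to a retained SNP with a larger
   effect.

LD clusters are the connected components of the r-squared > threshold graph
among criterion-1..5 survivors on the same chromosome; exactly one SNP per
cluster survives — the one with largest ``|ln OR|``, ties broken by the
lexicographically smallest rsID, which makes the output independent of the
input order.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from .model import GenotypeMatrix, RiskSNP, ValidationError

__all__ = ["ld_r2", "ld_r2_matrix", "prune_ld", "filter_risk_snps"]

REASON_DESCRIPTIONS = {
    1: "unspecified risk allele",
    2: "unspecified MAF or MAF in the excluded band",
    3: "published OR below the minimum effect size",
    4: "subtype-specific association only",
    5: "absent from the 1000 Genomes reference",
    6: "in linkage disequilibrium with a retained SNP",
}


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Genotypic r-squared: squared Pearson correlation of dosages over
    co-called individuals.  Returns NaN (undefined) with fewer than two
    co-observations or zero variance in either vector."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("dosage vectors differ in length")
    both = ~(np.isnan(a) | np.isnan(b))
    if both.sum() < 2:
        return float("nan")
    a, b = a[both], b[both]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_r2_matrix(matrix: GenotypeMatrix, rsids: list[str] | None = None) -> pd.DataFrame:
    """Pairwise r-squared for every pair of variants in ``matrix``."""
    ids = rsids if rsids is not None else [str(k) for k in matrix.variant_keys]
    m = len(ids)
    out = np.full((m, m), np.nan)
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = ld_r2(matrix.dosages[:, i], matrix.dosages[:, j])
    return pd.DataFrame(out, index=ids, columns=ids)


def _effect(snp: RiskSNP) -> float:
    if snp.or_published is None or snp.or_published <= 0:
        return 0.0
    return abs(math.log(snp.or_published))


def prune_ld(snps: list[RiskSNP], r2: pd.DataFrame, threshold: float = 0.8) -> list[RiskSNP]:
    """Keep exactly one SNP per LD cluster.

    Clusters are connected components of the graph with an edge wherever the
    pairwise r-squared strictly exceeds ``threshold`` (pairs at exactly the
    threshold stay unlinked) and both SNPs sit on the same chromosome.  The
    survivor of each cluster is the SNP with largest ``|ln OR|``; ties break
    to the smallest rsID.
    """
    by_rsid = {s.rsid: s for s in snps}
    if len(by_rsid) != len(snps):
        raise ValidationError("duplicate rsIDs in prune_ld input")
    graph = nx.Graph()
    graph.add_nodes_from(by_rsid)
    for i, a in enumerate(snps):
        for b in snps[i + 1 :]:
            if a.chrom is not None and b.chrom is not None and a.chrom != b.chrom:
                continue
            try:
                value = float(r2.loc[a.rsid, b.rsid])
            except KeyError:
                continue
            if not np.isnan(value) and value > threshold:
                graph.add_edge(a.rsid, b.rsid)
    keep = set()
    for component in nx.connected_components(graph):
        best = min(component, key=lambda r: (-_effect(by_rsid[r]), r))
        keep.add(best)
    return [s for s in snps if s.rsid in keep]


def filter_risk_snps(
    snps: list[RiskSNP],
    reference_genotypes: GenotypeMatrix | None = None,
    *,
    maf_band: tuple[float, float] = (0.45, 0.55),
    min_or: float = 1.04,
    r2_threshold: float = 0.8,
    r2: pd.DataFrame | None = None,
) -> tuple[list[RiskSNP], pd.DataFrame]:
    """Apply the six exclusion criteria.

    ``reference_genotypes`` supplies dosages (keyed by rsID) from which the
    pairwise r-squared for criterion 6 is computed; alternatively a
    precomputed ``r2`` matrix may be passed.  Returns the retained list and
    an exclusion report with one row per removed SNP carrying the first
    matching criterion number and its description.
    """
    seen = set()
    for s in snps:
        if s.rsid in seen:
            raise ValidationError(f"duplicate rsID {s.rsid}")
        seen.add(s.rsid)

    removals: list[dict] = []
    survivors: list[RiskSNP] = []
    low, high = maf_band
    for s in snps:
        reason = None
        if s.risk_allele is None:
            reason = 1
        elif s.maf is None or (low < s.maf < high):
            reason = 2
        elif s.or_published is not None and s.or_published < min_or:
            reason = 3
        elif s.subtype_specific:
            reason = 4
        elif not s.in_thousand_genomes:
            reason = 5
        if reason is None:
            survivors.append(s)
        else:
            removals.append({"rsid": s.rsid, "reason": reason, "description": REASON_DESCRIPTIONS[reason]})

    if r2 is None and reference_genotypes is not None:
        present = [s.rsid for s in survivors if s.rsid in reference_genotypes.variant_keys]
        sub = reference_genotypes.subset_variants(present)
        r2 = ld_r2_matrix(sub, present)
    if r2 is not None:
        kept = prune_ld(survivors, r2, threshold=r2_threshold)
        kept_ids = {s.rsid for s in kept}
        for s in survivors:
            if s.rsid not in kept_ids:
                removals.append({"rsid": s.rsid, "reason": 6, "description": REASON_DESCRIPTIONS[6]})
        survivors = kept
    report = pd.DataFrame(removals, columns=["rsid", "reason", "description"])
    return survivors, report
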