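"""High-risk gene panel screen with ClinVar pathogenicity.

The default panel covers the established high-risk genes for breast
(BRCA1/2), colorectal (APC, MLH1, MSH2, MSH6, MUTYH, PMS2) and prostate
(HOXB13) cancer.  The cohort side lists every rare missense / LoF variant
found in a panel gene together with its annotations; the reference side
reports, per gene, the probability that one reference individual carries at
least one ClinVar pathogenic / likely-pathogenic variant, using the same
carrier-probability aggregation as the gene-list comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .carrier import carrier_freq, carrier_probability
from .model import AnnotatedVariant, SiteCounts
from .prioritize import CascadeConfig, conservation_vote, deleteriousness_vote

__all__ = ["DEFAULT_PANEL", "PANEL_CAVEATS", "screen_high_risk", "reference_pathogenic_probability"]

DEFAULT_PANEL = ("BRCA1", "BRCA2", "APC", "MLH1", "MSH2", "MSH6", "MUTYH", "PMS2", "HOXB13")

#: Static caveats carried into reports (not logic).
PANEL_CAVEATS = {
    "MUTYH": "recessive predisposition gene; pathogenicity requires biallelic variants",
    "PMS2": "high-risk status under discussion",
    "HOXB13": "high-risk status under discussion",
}

_CLINVAR_DISPLAY = {
    "pathogenic": "Pathogenic",
    "likely_pathogenic": "Likely pathogenic",
    "uncertain": "US",
    "likely_benign": "Likely benign",
    "benign": "Benign",
    "not_provided": "Not provided",
    "absent": "-",
}


def screen_high_risk(
    variants: list[AnnotatedVariant],
    panel=DEFAULT_PANEL,
    maf_threshold: float = 0.001,
    frequency_source: str = "exac_nfe_nontcga",
    known_genes: set | None = None,
) -> pd.DataFrame:
    """List rare missense / LoF variants of the cohort within panel genes.

    A variant qualifies if its gene is on the panel, its consequence is
    missense or loss-of-function, and its frequency in the designated
    ``frequency_source`` is below ``maf_threshold`` (a variant with no
    frequency in that source counts as rare).  The frequency source is a
    parameter because reference exports disagree on which population the
    cut refers to.  Panel genes without a qualifying variant are reported as
    "Not found"; variants without an rsID appear as "No dbSNP".  Unknown
    panel symbols (not in ``known_genes`` when given) produce a warning but
    stay in the report with zero hits.
    """
    panel = list(panel)
    if known_genes is not None:
        for gene in panel:
            if gene not in known_genes:
                warnings.warn(f"panel gene {gene!r} not found among annotated genes", stacklevel=2)
    rows = []
    config = CascadeConfig()
    for gene in panel:
        hits = []
        for v in variants:
            if v.gene != gene or (v.consequence != "missense" and not v.is_lof):
                continue
            maf = v.maf_by_source.get(frequency_source)
            if maf is not None and maf >= maf_threshold:
                continue
            hits.append(v)
        caveat = PANEL_CAVEATS.get(gene, "")
        if not hits:
            rows.append(
                {
                    "gene": gene,
                    "snp_id": "Not found",
                    "chrom": "-",
                    "pos": "-",
                    "ref_alt": "-",
                    "prevalence": "-",
                    "cadd": "-",
                    "conservation_votes": "-",
                    "prediction_votes": "-",
                    "clinvar": "-",
                    "caveat": caveat,
                }
            )
            continue
        for v in hits:
            cons_k, cons_n, _ = conservation_vote(v, config)
            del_k, del_n, del_verdict = deleteriousness_vote(v)
            maf = v.maf_by_source.get(frequency_source)
            rows.append(
                {
                    "gene": gene,
                    "snp_id": v.rsid or "No dbSNP",
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref_alt": f"{v.ref_allele}/{v.alt_allele}",
                    "prevalence": "." if maf is None else f"{maf:.3g}",
                    "cadd": "-" if v.cadd_phred is None else f"{v.cadd_phred:g}",
                    "conservation_votes": f"{cons_k}" if cons_n == 3 else f"{cons_k}/{cons_n}",
                    "prediction_votes": f"{del_k}" if del_n == 10 else f"{del_k}/{del_n}",
                    "clinvar": _CLINVAR_DISPLAY.get(v.clinvar, v.clinvar) if v.clinvar_raw is None else v.clinvar_raw,
                    "caveat": caveat,
                }
            )
    return pd.DataFrame(rows)


def reference_pathogenic_probability(
    sites: list[SiteCounts],
    clinvar_by_key: dict,
    genes_by_key: dict,
    gene: str,
) -> dict:
    """Probability that a reference individual carries >= 1 ClinVar
    pathogenic / likely-pathogenic variant in ``gene``.

    Restricts the site-count table to the gene's pathogenic variants and
    aggregates their per-site carrier frequencies; a gene with no pathogenic
    variant reports P = 0.  Returns the probability together with total and
    pathogenic variant counts.
    """
    gene_sites = [s for s in sites if genes_by_key.get(s.variant_key) == gene]
    pathogenic = [
        s
        for s in gene_sites
        if clinvar_by_key.get(s.variant_key) in ("pathogenic", "likely_pathogenic")
    ]
    p = carrier_probability([carrier_freq(s) for s in pathogenic])
    return {
        "gene": gene,
        "total_variants": len(gene_sites),
        "pathogenic_variants": len(pathogenic),
        "p_reference": p,
        "p_reference_pct": f"{p * 100:.3f}%",
    }
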