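"""Variant-prioritization cascade: rarity, CADD, intolerance, conservation
and deleteriousness filters applied conjunctively with a per-stage audit.

The cascade reproduces a familial-cancer prioritization scheme:

* **MAF**: a variant passes only if its frequency is strictly below 0.1%
  in every available reference source (1000 Genomes, non-Finnish-European
  non-TCGA exome reference, local datasets).  A source without data counts
  as pass — unknown frequency is treated as rare.
* **CADD**: scaled PHRED-like score strictly greater than 10 (the top ~10%
  of possible substitutions).
* **Conservation**: votes from GERP (> 2.0), PhastCons (> 0.3) and PhyloP
  (>= 3.0, inclusive); pass at >= 2 votes.
* **Deleteriousness**: calls from ten missense predictors; pass when
  strictly more than half of the tools *with data* call the variant
  deleterious (with all ten available this is the ">= 6/10" rule).
* **Intolerance**: gene-intolerance ranks and the missense Z-score are
  recorded in the audit; they block only when explicit thresholds are
  configured.

Loss-of-function variants (stop gain/loss, splice site, frameshift indel)
skip the conservation and deleteriousness votes: missense predictors do not
score them.  They are filtered on MAF + CADD only.

Because the stages combine as a conjunction, the surviving set is the
intersection of per-stage pass sets and is invariant to stage order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MAF_SOURCES, PREDICTOR_TOOLS, AnnotatedVariant, ValidationError

__all__ = [
    "CascadeConfig",
    "StageAudit",
    "maf_filter",
    "cadd_filter",
    "conservation_vote",
    "deleteriousness_vote",
    "intolerance_screen",
    "fcvpp_cascade",
]

PASS, FAIL, NOT_EVALUATED = "pass", "fail", "not_evaluated"

#: Stages that can veto a variant ("hard" stages).
HARD_STAGES = ("maf", "cadd", "conservation", "deleteriousness")


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and missing-data policy for the cascade.

    ``strict_missing`` turns "not evaluated" verdicts on CADD/conservation/
    deleteriousness into failures; by default missing annotations pass
    through.  ``intolerance_thresholds`` maps score names (``esp6500``,
    ``exac``, ``local``, ``missense_z``) to minimum acceptable values; when
    non-empty the intolerance stage becomes a hard filter.
    """

    maf_threshold: float = 0.001
    cadd_threshold: float = 10.0
    gerp_threshold: float = 2.0
    phastcons_threshold: float = 0.3
    phylop_threshold: float = 3.0
    conservation_min_votes: int = 2
    strict_missing: bool = False
    intolerance_thresholds: dict = field(default_factory=dict)


def maf_filter(variant: AnnotatedVariant, threshold: float = 0.001) -> str:
    """Pass iff the MAF is strictly below ``threshold`` in every available
    source; sources without data count as pass; no sources at all means the
    stage cannot be evaluated."""
    available = [v for v in variant.maf_by_source.values() if v is not None]
    if not available:
        return NOT_EVALUATED
    return PASS if all(v < threshold for v in available) else FAIL


def cadd_filter(variant: AnnotatedVariant, threshold: float = 10.0) -> str:
    """Pass iff the scaled CADD score is strictly greater than ``threshold``."""
    if variant.cadd_phred is None:
        return NOT_EVALUATED
    return PASS if variant.cadd_phred > threshold else FAIL


def conservation_vote(
    variant: AnnotatedVariant, config: CascadeConfig = CascadeConfig()
) -> tuple[int, int, str]:
    """Count conserved-position votes among the available conservation tools.

    Returns ``(votes, n_available, verdict)``.  GERP and PhastCons use
    strict thresholds, PhyloP is inclusive.  Pass at >= 2 votes; with no
    tool available the stage is not evaluated.
    """
    votes, available = 0, 0
    if variant.gerp is not None:
        available += 1
        votes += variant.gerp > config.gerp_threshold
    if variant.phastcons is not None:
        available += 1
        votes += variant.phastcons > config.phastcons_threshold
    if variant.phylop is not None:
        available += 1
        votes += variant.phylop >= config.phylop_threshold
    if available == 0:
        return 0, 0, NOT_EVALUATED
    return int(votes), available, (PASS if votes >= config.conservation_min_votes else FAIL)


def deleteriousness_vote(variant: AnnotatedVariant) -> tuple[int, int, str]:
    """Count deleterious calls among the ten predictors.

    Returns ``(k, n_available, verdict)`` with pass iff ``k > n/2`` —
    strictly more than half of the tools with data (>= 6/10 when all ten
    are available)."""
    calls = [variant.predictor_calls[t] for t in PREDICTOR_TOOLS]
    n = sum(1 for c in calls if c != "missing")
    k = sum(1 for c in calls if c == "deleterious")
    if n == 0:
        return 0, 0, NOT_EVALUATED
    return k, n, (PASS if k > n / 2 else FAIL)


def intolerance_screen(
    variant: AnnotatedVariant, config: CascadeConfig = CascadeConfig()
) -> tuple[dict, str]:
    """Attach intolerance ranks and the missense Z-score to the audit.

    Non-blocking by default: the verdict is "pass" unless thresholds are
    configured, in which case every configured score with data must meet its
    minimum."""
    record = dict(variant.intolerance_ranks)
    if not config.intolerance_thresholds:
        return record, PASS
    verdicts = []
    for name, minimum in config.intolerance_thresholds.items():
        value = record.get(name)
        if value is not None:
            verdicts.append(value >= minimum)
    if not verdicts:
        return record, NOT_EVALUATED
    return record, (PASS if all(verdicts) else FAIL)


@dataclass
class StageAudit:
    """Per-variant stage verdicts and the final decision."""

    variant: AnnotatedVariant
    stages: dict
    conservation_votes: str  # "k/n" over available tools
    deleteriousness_votes: str
    final: bool

    def row(self) -> dict:
        chrom, pos, ref, alt = self.variant.key
        return {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene": self.variant.gene,
            "consequence": self.variant.consequence,
            **{f"stage_{name}": verdict for name, verdict in self.stages.items()},
            "conservation_votes": self.conservation_votes,
            "deleteriousness_votes": self.deleteriousness_votes,
            "final": "pass" if self.final else "fail",
        }


def _evaluate(variant: AnnotatedVariant, config: CascadeConfig) -> StageAudit:
    stages: dict = {}
    stages["maf"] = maf_filter(variant, config.maf_threshold)
    stages["cadd"] = cadd_filter(variant, config.cadd_threshold)
    if variant.is_lof:
        # Missense predictors and positional conservation votes do not apply
        # to truncating variants; these stages are recorded as not evaluated
        # and never veto.
        cons = (0, 0, NOT_EVALUATED)
        dele = (0, 0, NOT_EVALUATED)
        stages["conservation"] = NOT_EVALUATED
        stages["deleteriousness"] = NOT_EVALUATED
        lof_exempt = True
    else:
        cons = conservation_vote(variant, config)
        dele = deleteriousness_vote(variant)
        stages["conservation"] = cons[2]
        stages["deleteriousness"] = dele[2]
        lof_exempt = False
    _, intol_verdict = intolerance_screen(variant, config)
    stages["intolerance"] = intol_verdict

    final = True
    for name in HARD_STAGES:
        verdict = stages[name]
        if verdict == FAIL:
            final = False
        elif verdict == NOT_EVALUATED and config.strict_missing and not (
            lof_exempt and name in ("conservation", "deleteriousness")
        ):
            final = False
    if stages["intolerance"] == FAIL:
        final = False
    return StageAudit(
        variant=variant,
        stages=stages,
        conservation_votes=f"{cons[0]}/{cons[1]}",
        deleteriousness_votes=f"{dele[0]}/{dele[1]}",
        final=final,
    )


def fcvpp_cascade(
    variants: list[AnnotatedVariant],
    gene_list: set[str] | list[str],
    consequence_class: str,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[StageAudit], list[AnnotatedVariant]]:
    """Run the full cascade over ``variants``.

    The variant set is first restricted to genes in ``gene_list`` and to the
    requested consequence class (``"non_synonymous"`` keeps missense
    variants, ``"lof"`` keeps stop gain/loss, splice-site and frameshift
    indels); the stage filters are then applied conjunctively.  Returns the
    per-variant audit (one entry per in-scope variant, each with a final
    verdict) and the survivors.
    """
    genes = set(gene_list)
    if not genes:
        raise ValidationError("empty gene list")
    if consequence_class not in ("non_synonymous", "lof"):
        raise ValidationError(f"consequence_class must be 'non_synonymous' or 'lof', got {consequence_class!r}")
    in_scope = [
        v
        for v in variants
        if v.gene in genes
        and ((consequence_class == "non_synonymous" and v.consequence == "missense") or (consequence_class == "lof" and v.is_lof))
    ]
    audits = [_evaluate(v, config) for v in in_scope]
    survivors = [a.variant for a in audits if a.final]
    return audits, survivors


def audit_frame(audits: list[StageAudit]) -> pd.DataFrame:
    return pd.DataFrame([a.row() for a in audits])
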