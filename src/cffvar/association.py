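"""Per-SNP risk-allele-frequency comparison between cohort and reference.

Each SNP contributes a 2x2 allele table (cohort risk / cohort other /
reference risk / reference other).  The odds ratio is the cross-product
ratio — identical to the coefficient of a logistic regression of group
membership on allele identity with each chromosome as one observation —
with Wald inference on the log scale.  Multiple testing is handled by
Bonferroni adjustment of the significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import GenotypeMatrix, RiskSNP, ValidationError

__all__ = ["AlleleTable2x2", "TwoByTwoResult", "two_by_two_or", "bonferroni_level", "allele_scan"]

Z_975 = 1.959964  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class AlleleTable2x2:
    """Cohort risk (a), cohort other (b), reference risk (c), reference other (d)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 cells must be >= 0")


@dataclass(frozen=True)
class TwoByTwoResult:
    odds_ratio: float
    se_log_or: float
    ci_low: float
    ci_high: float
    p: float
    flagged: bool = False  # True when a zero cell made the OR undefined


def two_by_two_or(table: AlleleTable2x2) -> TwoByTwoResult:
    """Closed-form odds ratio with Wald CI and p for one 2x2 table.

    OR = ad/bc, SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d), CI on the log
    scale, two-sided normal p.  Any zero cell yields an undefined (NaN)
    result flagged for the report; no continuity correction is applied.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return TwoByTwoResult(np.nan, np.nan, np.nan, np.nan, np.nan, flagged=True)
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TwoByTwoResult(
        odds_ratio=float(np.exp(log_or)),
        se_log_or=float(se),
        ci_low=float(np.exp(log_or - Z_975 * se)),
        ci_high=float(np.exp(log_or + Z_975 * se)),
        p=float(p),
    )


def bonferroni_level(alpha: float = 0.05, m: int = 1) -> tuple[float, float]:
    """Bonferroni-adjusted significance level: alpha/m.

    Returns (full precision, display value rounded to 4 decimals)."""
    if m < 1:
        raise ValidationError(f"number of tests must be >= 1, got {m}")
    level = alpha / m
    return level, round(level, 4)


def allele_scan(
    cohort: GenotypeMatrix,
    reference: pd.DataFrame,
    risk_snps: list[RiskSNP],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP comparison of cohort vs reference risk-allele frequency.

    ``cohort`` dosages must be keyed by rsID and oriented to the risk allele.
    ``reference`` carries one row per rsID with columns ``af`` (risk-allele
    frequency) and ``an`` (allele number); risk-allele counts are
    reconstructed as ``round(af * an)``.  SNPs missing from the cohort are
    emitted with undefined fields rather than dropped.  Rows are flagged at
    the nominal 0.05 level and at the Bonferroni level ``alpha / n_snps``.
    """
    ref = reference.set_index("rsid") if "rsid" in reference.columns else reference
    level, level_display = bonferroni_level(alpha, len(risk_snps))
    rows = []
    for snp in risk_snps:
        row = {
            "rsid": snp.rsid,
            "gene": snp.gene or "",
            "risk_allele": snp.risk_allele or ".",
            "freq_reference": np.nan,
            "freq_cohort": np.nan,
            "or": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
            "nominal": False,
            "bonferroni_significant": False,
        }
        if snp.rsid not in ref.index:
            raise ValidationError(f"SNP {snp.rsid} missing from the reference frequency table")
        af = float(ref.loc[snp.rsid, "af"])
        an = int(ref.loc[snp.rsid, "an"])
        c = round(af * an)
        d = an - c
        row["freq_reference"] = af
        if snp.rsid in cohort.variant_keys:
            dosage = cohort.column(snp.rsid)
            called = ~np.isnan(dosage)
            n_alleles = 2 * int(called.sum())
            if n_alleles > 0:
                a = float(np.nansum(dosage))
                b = n_alleles - a
                row["freq_cohort"] = a / n_alleles
                res = two_by_two_or(AlleleTable2x2(a, b, c, d))
                row.update(
                    {
                        "or": res.odds_ratio,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p": res.p,
                        "nominal": bool(res.p < 0.05) if np.isfinite(res.p) else False,
                        "bonferroni_significant": bool(res.p < level) if np.isfinite(res.p) else False,
                    }
                )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_level"] = level
    out.attrs["bonferroni_level_display"] = level_display
    return out
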