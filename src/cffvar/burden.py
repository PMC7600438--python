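"""Polygenic risk-allele burden: per-individual totals, reference-defined
quartiles, per-quartile odds ratios and the trend test.

Every individual's burden is the unweighted sum of risk-allele dosages over
the SNP panel.  Quartile boundaries come from the reference population
(empirical 25th/50th/75th percentiles floored to integers, bins closed as
"<= c1", "c1+1 .. c2", ..., "> c3" so ties fall in the lower bin).  Each
upper quartile is compared to quartile 1 by the 2x2 cross-product odds
ratio, and the trend test is a logistic regression of cohort membership on
the quartile index 1..4 treated as a continuous covariate, with a two-sided
Wald p on the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import AlleleTable2x2, two_by_two_or
from .model import GenotypeMatrix, QuartileSummary, RiskSNP, ValidationError

__all__ = [
    "count_risk_alleles",
    "quartile_bins",
    "assign_quartiles",
    "quartile_table",
    "quartile_table_from_counts",
    "trend_test",
    "trend_test_from_counts",
    "TrendResult",
]


def count_risk_alleles(
    matrix: GenotypeMatrix,
    risk_snps: list[RiskSNP],
    missing: str = "impute",
) -> np.ndarray:
    """Per-individual risk-allele totals over the SNP panel.

    Dosages must be keyed by rsID and oriented to the risk allele.  Missing
    dosages either contribute the panel expectation ``2 * MAF`` of that SNP
    (``missing="impute"``, the default) or are dropped (``missing="drop"``).
    An individual with no called SNP at all is reported as NaN.
    """
    if missing not in ("impute", "drop"):
        raise ValidationError(f"missing policy must be 'impute' or 'drop', got {missing!r}")
    rsids = [s.rsid for s in risk_snps]
    sub = matrix.subset_variants([r for r in rsids if r in matrix.variant_keys])
    if sub.n_variants != len(rsids):
        absent = sorted(set(rsids) - set(sub.variant_keys))
        raise ValidationError(f"panel SNPs missing from the matrix: {absent[:5]}")
    d = sub.dosages.copy()
    all_missing = np.isnan(d).all(axis=1)
    if missing == "impute":
        mafs = np.array([s.maf if s.maf is not None else np.nan for s in risk_snps])
        if np.isnan(mafs[np.isnan(d).any(axis=0)]).any():
            raise ValidationError("cannot impute: a SNP with missing calls has no panel MAF")
        fill = np.broadcast_to(2.0 * mafs, d.shape)
        d = np.where(np.isnan(d), fill, d)
        totals = d.sum(axis=1)
    else:
        totals = np.nansum(d, axis=1)
    totals = totals.astype(float)
    totals[all_missing] = np.nan
    return totals


def quartile_bins(reference_totals: np.ndarray) -> tuple[int, int, int]:
    """Integer cutpoints at the reference 25th/50th/75th percentiles.

    Cutpoints are floored so that bins read as ``<= c1``, ``c1+1 .. c2``,
    ``c2+1 .. c3`` and ``> c3``; by construction the reference population
    splits into approximately equal quarters (exactly equal up to ties).
    """
    totals = np.asarray(reference_totals, dtype=float)
    totals = totals[~np.isnan(totals)]
    if len(totals) < 8:
        raise ValidationError("need at least 8 reference individuals to define quartiles")
    if totals.min() == totals.max():
        raise ValidationError("degenerate reference distribution: all totals equal")
    c1, c2, c3 = (int(np.floor(np.percentile(totals, q))) for q in (25, 50, 75))
    return c1, c2, c3


def assign_quartiles(totals: np.ndarray, bins: tuple[int, int, int]) -> np.ndarray:
    """Quartile index 1..4 for each total (NaN totals get 0)."""
    c1, c2, c3 = bins
    t = np.asarray(totals, dtype=float)
    q = np.zeros(len(t), dtype=int)
    valid = ~np.isnan(t)
    q[valid] = 1 + (t[valid] > c1).astype(int) + (t[valid] > c2).astype(int) + (t[valid] > c3).astype(int)
    return q


def bin_labels(bins: tuple[int, int, int]) -> list[str]:
    c1, c2, c3 = bins
    return [f"<={c1}", f"{c1 + 1}-{c2}", f"{c2 + 1}-{c3}", f">{c3}"]


def _quartile_counts(totals, bins) -> list[int]:
    q = assign_quartiles(totals, bins)
    return [int((q == i).sum()) for i in (1, 2, 3, 4)]


def quartile_table(
    reference_totals: np.ndarray,
    cohort_totals: np.ndarray,
    bins: tuple[int, int, int],
) -> QuartileSummary:
    """Quartile-by-cohort counts with per-quartile ORs and the trend test."""
    ref_counts = _quartile_counts(reference_totals, bins)
    coh_counts = _quartile_counts(cohort_totals, bins)
    summary = quartile_table_from_counts(ref_counts, coh_counts, bins)
    return summary


def quartile_table_from_counts(
    reference_counts: list[int],
    cohort_counts: list[int],
    bins: tuple[int, int, int] | None = None,
    labels: list[str] | None = None,
) -> QuartileSummary:
    """Build the quartile summary directly from 2x4 counts.

    For quartile q in {2,3,4} the OR against quartile 1 is the cross-product
    of the 2x2 table (cohort_q, cohort_1, reference_q, reference_1); an
    empty stratum on either side leaves that row undefined.  The trend row
    is the Wald p of the quartile-index slope.
    """
    if len(reference_counts) != 4 or len(cohort_counts) != 4:
        raise ValidationError("expected 4 quartile counts per group")
    if labels is None:
        labels = bin_labels(bins) if bins is not None else ["Q1", "Q2", "Q3", "Q4"]
    ors, lows, highs, ps = [1.0], [np.nan], [np.nan], [np.nan]
    for q in (1, 2, 3):
        res = two_by_two_or(
            AlleleTable2x2(cohort_counts[q], cohort_counts[0], reference_counts[q], reference_counts[0])
        )
        ors.append(res.odds_ratio)
        lows.append(res.ci_low)
        highs.append(res.ci_high)
        ps.append(res.p)
    trend = trend_test_from_counts(reference_counts, cohort_counts)
    return QuartileSummary(
        cutpoints=tuple(bins) if bins is not None else (0, 0, 0),
        labels=labels,
        reference_counts=list(map(int, reference_counts)),
        cohort_counts=list(map(int, cohort_counts)),
        odds_ratios=ors,
        ci_low=lows,
        ci_high=highs,
        p_values=ps,
        trend_slope=trend.slope,
        trend_p=trend.p,
    )


@dataclass(frozen=True)
class TrendResult:
    slope: float
    se: float
    p: float
    converged: bool = True


def trend_test_from_counts(reference_counts, cohort_counts) -> TrendResult:
    """Logistic trend test on aggregated quartile counts.

    Fits membership (cohort=1) ~ quartile index with the index coded 1..4 as
    a single continuous covariate, by maximum likelihood; reports the slope
    and its two-sided Wald p.  Separation or non-convergence is flagged
    rather than raised.
    """
    x, y, w = [], [], []
    for q in range(4):
        for label, count in ((0, reference_counts[q]), (1, cohort_counts[q])):
            if count > 0:
                x.append(float(q + 1))
                y.append(label)
                w.append(float(count))
    if len(set(y)) < 2:
        return TrendResult(np.nan, np.nan, np.nan, converged=False)
    exog = sm.add_constant(np.array(x))
    model = sm.GLM(np.array(y, dtype=float), exog, family=sm.families.Binomial(), freq_weights=np.array(w))
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    separated = False
    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            fit = model.fit()
        separated = any(issubclass(c.category, PerfectSeparationWarning) for c in caught)
    except Exception:  # noqa: BLE001 - complete separation can raise inside IRLS
        return TrendResult(np.nan, np.nan, np.nan, converged=False)
    converged = bool(getattr(fit, "converged", True)) and np.isfinite(fit.bse[1]) and not separated
    return TrendResult(float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]), converged)


def trend_test(
    reference_totals: np.ndarray,
    cohort_totals: np.ndarray,
    bins: tuple[int, int, int],
) -> TrendResult:
    """Trend test from raw totals (quartiles assigned by ``bins``)."""
    return trend_test_from_counts(
        _quartile_counts(reference_totals, bins), _quartile_counts(cohort_totals, bins)
    )
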