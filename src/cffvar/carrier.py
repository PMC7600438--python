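"""Carrier-probability aggregation and the BCa bootstrap odds-ratio CI.

For a set of k qualifying variants with per-site carrier frequencies
q_i = (AC_i - Hom_i) / (AN_i / 2), the probability that one individual
carries at least one of them, assuming independent sites, is

    P = 1 - prod_i (1 - q_i).

The cohort-side probability is the observed fraction of individuals with a
non-zero dosage at any qualifying variant.  The two probabilities compare
as an odds ratio

    OR = P_cohort (1 - P_ref) / [(1 - P_cohort) P_ref],

whose 95% CI comes from a bias-corrected and accelerated (BCa) bootstrap
over cohort individuals with the reference probability held fixed (the
reference is orders of magnitude larger, so its sampling error is
negligible; resampling the small cohort is also the only way a zero lower
bound can arise).  The bootstrap statistic is ln OR; replicates with a
resampled carrier fraction of 0 or 1 map to -inf/+inf and occupy the
quantile extremes rather than being discarded.  Intervals are read off the
replicate distribution with the inverse-empirical-CDF (type-1) quantile so
results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CarrierResult, GenotypeMatrix, SiteCounts, ValidationError

__all__ = [
    "carrier_freq",
    "carrier_probability",
    "cohort_carrier_probability",
    "carrier_or",
    "bca_ci",
    "table3_report",
]


def carrier_freq(site: SiteCounts) -> float:
    """Fraction of reference individuals carrying >= 1 alternate allele:
    (AC - Hom) / (AN / 2)."""
    if site.an <= 0:
        raise ValidationError("AN must be positive")
    return (site.ac - site.hom) / (site.an / 2.0)


def carrier_probability(q_list) -> float:
    """P = 1 - prod(1 - q_i) over per-site carrier frequencies.

    An empty list yields P = 0 (no qualifying variants, k = 0)."""
    qs = np.asarray(list(q_list), dtype=float)
    if qs.size == 0:
        return 0.0
    if ((qs < 0) | (qs > 1)).any():
        raise ValidationError("carrier frequencies must lie in [0,1]")
    return float(1.0 - np.prod(1.0 - qs))


def cohort_carrier_probability(
    matrix: GenotypeMatrix, qualifying_variants
) -> tuple[float, np.ndarray]:
    """Observed carrier fraction in the cohort plus the per-individual
    carrier indicator vector (retained for bootstrapping).

    An individual is a carrier if any qualifying variant has a non-zero
    called dosage; missing calls count as non-carrying at that site."""
    if matrix.n_individuals == 0:
        raise ValidationError("empty cohort")
    keys = list(qualifying_variants)
    if keys:
        sub = matrix.subset_variants(keys)
        with np.errstate(invalid="ignore"):
            indicators = np.nan_to_num(sub.dosages, nan=0.0).sum(axis=1) > 0
    else:
        indicators = np.zeros(matrix.n_individuals, dtype=bool)
    indicators = indicators.astype(float)
    return float(indicators.mean()), indicators


def carrier_or(p_cohort: float, p_reference: float) -> float:
    """Odds ratio of the two carrier probabilities.

    Defined (finite) when both probabilities are interior; a reference
    probability of 0 or 1 is an error, a cohort probability of 0 or 1 maps
    to 0 / inf."""
    if not (0.0 < p_reference < 1.0):
        raise ValidationError(f"reference probability must be in (0,1), got {p_reference}")
    if p_cohort == 0.0:
        return 0.0
    if p_cohort == 1.0:
        return float("inf")
    return (p_cohort * (1.0 - p_reference)) / ((1.0 - p_cohort) * p_reference)


def _log_or(p: np.ndarray, p_reference: float) -> np.ndarray:
    """ln OR of p vs p_reference; p=0 -> -inf, p=1 -> +inf."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        return np.log(p) - np.log1p(-p) + np.log1p(-p_reference) - np.log(p_reference)


def _type1_quantile(sorted_values: np.ndarray, alpha: float) -> float:
    """Inverse-empirical-CDF quantile of pre-sorted values."""
    n = len(sorted_values)
    idx = int(np.ceil(alpha * n)) - 1
    return float(sorted_values[min(max(idx, 0), n - 1)])


@dataclass(frozen=True)
class BcaInterval:
    ci_low: float
    ci_high: float
    z0: float
    accel: float
    theta_hat: float  # ln OR point estimate
    flags: tuple = ()


def bca_ci(
    carrier_indicators: np.ndarray,
    p_reference: float,
    n_boot: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    z0: float | None = None,
    accel: float | None = None,
) -> BcaInterval:
    """BCa bootstrap CI for the carrier odds ratio.

    Individuals (the 0/1 indicator vector) are resampled with replacement
    ``n_boot`` times; each replicate recomputes the cohort carrier fraction
    and the ln OR against the fixed ``p_reference``.  The bias correction is
    z0 = Phi^{-1}(#{theta* < theta_hat} / B) and the acceleration comes from
    the jackknife third-moment formula; ``z0``/``accel`` can be forced (e.g.
    to 0) to reduce the interval to the plain percentile method.  The seed
    is mandatory so intervals are reproducible bit-exactly.

    Returns the interval on the OR scale; a lower bound of 0.0 or an upper
    bound of inf arises from replicates with carrier fraction 0 or 1.
    """
    ind = np.asarray(carrier_indicators, dtype=float)
    n = len(ind)
    if n < 2:
        raise ValidationError("need at least 2 individuals to bootstrap")
    if n_boot < 1000:
        raise ValidationError(f"n_boot must be >= 1000, got {n_boot}")
    if seed is None:
        raise ValidationError("a seed is mandatory for reproducible intervals")
    flags: list[str] = []
    theta_hat = float(_log_or(ind.mean(), p_reference))

    if ind.min() == ind.max():
        # Degenerate input: every resample reproduces the point estimate.
        value = float(np.exp(theta_hat))
        return BcaInterval(value, value, np.nan, np.nan, theta_hat, flags=("degenerate",))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    p_star = ind[idx].mean(axis=1)
    theta_star = _log_or(p_star, p_reference)

    if np.all(theta_star == theta_star[0]):
        value = float(np.exp(theta_star[0]))
        return BcaInterval(value, value, np.nan, np.nan, theta_hat, flags=("degenerate_replicates",))

    if z0 is None:
        prop = float((theta_star < theta_hat).mean())
        if prop <= 0.0 or prop >= 1.0:
            prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
            flags.append("z0_clamped")
        z0 = float(stats.norm.ppf(prop))
    if accel is None:
        theta_jack = _log_or((ind.sum() - ind) / (n - 1), p_reference)
        if not np.isfinite(theta_jack).all():
            # A leave-one-out estimate hit the boundary; fall back to the
            # jackknife on the carrier fraction itself (same monotone scale).
            theta_jack = (ind.sum() - ind) / (n - 1)
            flags.append("accel_on_fraction_scale")
        diffs = theta_jack.mean() - theta_jack
        denom = (diffs**2).sum() ** 1.5
        accel = float((diffs**3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    z_lo = stats.norm.ppf(alpha / 2.0)
    z_hi = stats.norm.ppf(1.0 - alpha / 2.0)
    adjusted = []
    for z in (z_lo, z_hi):
        denom = 1.0 - accel * (z0 + z)
        if denom <= 0:
            adjusted.append(1.0 if z > 0 else 0.0)
            flags.append("bca_mapping_clamped")
        else:
            adjusted.append(float(stats.norm.cdf(z0 + (z0 + z) / denom)))
    theta_sorted = np.sort(theta_star)
    lo = _type1_quantile(theta_sorted, adjusted[0])
    hi = _type1_quantile(theta_sorted, adjusted[1])
    return BcaInterval(
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        z0=float(z0),
        accel=float(accel),
        theta_hat=theta_hat,
        flags=tuple(flags),
    )


def carrier_comparison(
    matrix: GenotypeMatrix,
    qualifying_variants,
    reference_sites: list[SiteCounts],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> CarrierResult:
    """End-to-end comparison for one stratum: cohort carrier fraction vs the
    aggregated reference carrier probability, with a BCa CI on the OR."""
    p_ref = carrier_probability([carrier_freq(s) for s in reference_sites])
    p_coh, indicators = cohort_carrier_probability(matrix, qualifying_variants)
    flags: tuple = ()
    if 0.0 < p_ref < 1.0:
        or_value = carrier_or(p_coh, p_ref)
        interval = bca_ci(indicators, p_ref, n_boot=n_boot, seed=seed)
        ci_low, ci_high, flags = interval.ci_low, interval.ci_high, interval.flags
    else:
        or_value, ci_low, ci_high = None, None, None
        flags = ("reference_probability_boundary",)
    return CarrierResult(
        k=len(list(qualifying_variants)),
        p_cohort=p_coh,
        p_reference=p_ref,
        or_value=or_value,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        seed=seed,
        flags=flags,
    )


def table3_report(strata: list[dict], n_boot: int = 10_000, seed: int | None = None) -> pd.DataFrame:
    """Summary table across (gene-list source x consequence class) strata.

    Each stratum dict needs: ``source``, ``consequence_class``, ``matrix``
    (cohort GenotypeMatrix), ``cohort_variants`` (qualifying variant keys),
    ``reference_sites`` (SiteCounts of the qualifying reference variants).
    Probabilities are displayed as whole percentages alongside the raw
    values; a stratum with no cohort variants reports P = 0% and omits the
    OR.
    """
    rows = []
    for i, stratum in enumerate(strata):
        cohort_variants = list(stratum["cohort_variants"])
        reference_sites = list(stratum["reference_sites"])
        stratum_seed = None if seed is None else seed + i
        if cohort_variants:
            result = carrier_comparison(
                stratum["matrix"], cohort_variants, reference_sites, n_boot=n_boot, seed=stratum_seed
            )
        else:
            p_ref = carrier_probability([carrier_freq(s) for s in reference_sites])
            result = CarrierResult(0, 0.0, p_ref, None, None, None, n_boot, stratum_seed,
                                   flags=("no_cohort_variants",))
        rows.append(
            {
                "source": stratum["source"],
                "class": stratum["consequence_class"],
                "cohort_n_variants": result.k,
                "p_cohort": result.p_cohort,
                "p_cohort_pct": f"{round(result.p_cohort * 100):.0f} %",
                "reference_n_variants": len(reference_sites),
                "p_reference": result.p_reference,
                "p_reference_pct": f"{round(result.p_reference * 100):.0f} %",
                "or": np.nan if result.or_value is None else result.or_value,
                "ci_low": np.nan if result.ci_low is None else result.ci_low,
                "ci_high": np.nan if result.ci_high is None else result.ci_high,
                "flags": ";".join(result.flags),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_boot"] = n_boot
    out.attrs["seed"] = seed
    return out
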