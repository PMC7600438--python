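"""Variant- and site-level quality filters plus the pairwise relatedness check.

Genotype calls backed by fewer than 5 reads are set missing; variants whose
QUAL is not strictly above 20 are dropped.  Site-level analysis keeps only
positions covered by at least 10 reads in at least 90% of samples.  The
relatedness check compares every pair of individuals by the fraction of
co-called variants with identical dosage; suspiciously concordant pairs are
reported, never removed automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, ValidationError

__all__ = ["SiteDepthTable", "variant_qc", "site_mask", "pairwise_relatedness"]


@dataclass
class SiteDepthTable:
    """Per-call read depths (variants x individuals) and per-variant QUAL."""

    depths: pd.DataFrame  # rows: variant labels, columns: individual ids
    qual: pd.Series  # indexed like depths rows

    def __post_init__(self) -> None:
        if not self.depths.index.equals(self.qual.index):
            raise ValidationError("depth rows and QUAL index are misaligned")
        if (self.depths.to_numpy() < 0).any():
            raise ValidationError("read depths must be >= 0")


def _check_alignment(matrix: GenotypeMatrix, depth: SiteDepthTable) -> np.ndarray:
    """Return depths as (individuals x variants), failing on misalignment."""
    if list(depth.depths.columns) != list(matrix.individual_ids):
        raise ValidationError("depth table individuals do not match the genotype matrix")
    if len(depth.depths.index) != matrix.n_variants:
        raise ValidationError(
            f"depth table has {len(depth.depths.index)} variants, matrix has {matrix.n_variants}"
        )
    return depth.depths.to_numpy().T


def variant_qc(
    matrix: GenotypeMatrix,
    depth_table: SiteDepthTable,
    min_depth: int = 5,
    min_qual: float = 20.0,
) -> GenotypeMatrix:
    """Apply the per-call depth filter and the per-variant QUAL filter.

    A call with depth below ``min_depth`` (minimum of 5 reads) becomes
    missing; a variant with QUAL not strictly greater than ``min_qual``
    ("higher than 20") is dropped entirely.  Dosages are never altered other
    than to missing.
    """
    depths = _check_alignment(matrix, depth_table)
    dosages = matrix.dosages.copy()
    dosages[depths < min_depth] = np.nan
    keep = depth_table.qual.to_numpy() > min_qual
    keys = [k for k, ok in zip(matrix.variant_keys, keep) if ok]
    return GenotypeMatrix(matrix.individual_ids, keys, dosages[:, keep])


def site_mask(
    depth_table: SiteDepthTable, min_depth: int = 10, min_fraction: float = 0.9
) -> pd.Series:
    """Boolean per-variant mask: covered by >= ``min_depth`` reads in at
    least ``min_fraction`` of samples (both bounds inclusive)."""
    depths = depth_table.depths.to_numpy()
    fraction = (depths >= min_depth).mean(axis=1) if depths.shape[1] else np.zeros(len(depths))
    return pd.Series(fraction >= min_fraction, index=depth_table.depths.index, name="included")


def pairwise_relatedness(
    matrix: GenotypeMatrix, flag_threshold: float = 0.9
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype-concordance fractions for every pair of individuals.

    Concordance is the fraction of variants called in both individuals where
    the dosages are identical.  Returns the symmetric concordance table
    (NaN where a pair shares no co-called variant) and a report of pairs at
    or above ``flag_threshold`` plus undefined pairs.
    """
    if matrix.n_individuals < 2:
        raise ValidationError("relatedness needs at least 2 individuals")
    d = matrix.dosages
    n = matrix.n_individuals
    called = ~np.isnan(d)
    concordance = np.full((n, n), np.nan)
    flagged = []
    for i in range(n):
        for j in range(i, n):
            both = called[i] & called[j]
            total = int(both.sum())
            if total == 0:
                value = np.nan
            else:
                value = float((d[i, both] == d[j, both]).mean())
            concordance[i, j] = concordance[j, i] = value
            if i < j:
                if np.isnan(value):
                    flagged.append((matrix.individual_ids[i], matrix.individual_ids[j], np.nan, "undefined"))
                elif value >= flag_threshold:
                    flagged.append((matrix.individual_ids[i], matrix.individual_ids[j], value, "high_concordance"))
    table = pd.DataFrame(concordance, index=matrix.individual_ids, columns=matrix.individual_ids)
    report = pd.DataFrame(flagged, columns=["individual_a", "individual_b", "concordance", "flag"])
    return table, report
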