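"""Core domain types shared by every stage of the pipeline.

The analysis moves four kinds of object around:

* :class:`AnnotatedVariant` — one variant together with the annotations the
  prioritization cascade consumes (population frequencies, CADD, conservation
  scores, ten missense-predictor calls, ClinVar significance).
* :class:`SiteCounts` — a reference-population site record (allele count AC,
  homozygote count Hom, allele number AN), the unit from which per-site
  carrier frequencies are derived.
* :class:`RiskSNP` — one GWAS hit with the metadata the six exclusion
  criteria need (risk allele, MAF, published OR, subtype flag, 1000-Genomes
  presence).
* :class:`GenotypeMatrix` — an individuals x variants dosage table with
  dosages in {0, 1, 2} and NaN for missing calls.

Coordinates are 1-based and fully closed, matching VCF; all joins are on
``(chrom, pos, ref, alt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "CONSEQUENCES",
    "LOF_CONSEQUENCES",
    "PREDICTOR_TOOLS",
    "CLINVAR_CATEGORIES",
    "CLINVAR_SEVERITY",
    "VariantKey",
    "AnnotatedVariant",
    "SiteCounts",
    "RiskSNP",
    "GenotypeMatrix",
    "QuartileSummary",
    "CarrierResult",
]


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed as the format it claims to be."""


#: Closed set of functional consequence labels.
CONSEQUENCES = frozenset(
    {"missense", "stop_gain", "stop_loss", "splice_site", "frameshift_indel", "other"}
)

#: The loss-of-function subset: stop gain/loss, splice-site and frameshift indels.
LOF_CONSEQUENCES = frozenset({"stop_gain", "stop_loss", "splice_site", "frameshift_indel"})

#: The ten missense deleteriousness predictors, in canonical order.
PREDICTOR_TOOLS = (
    "sift",
    "polyphen2_hdiv",
    "polyphen2_hvar",
    "lrt",
    "mutation_taster",
    "mutation_assessor",
    "fathmm",
    "metasvm",
    "metalr",
    "provean",
)

#: Valid normalized predictor calls.
PREDICTOR_CALLS = frozenset({"deleterious", "tolerated", "missing"})

#: ClinVar significance buckets recognised by the screen.
CLINVAR_CATEGORIES = (
    "pathogenic",
    "likely_pathogenic",
    "uncertain",
    "likely_benign",
    "benign",
    "not_provided",
    "absent",
)

#: Severity rank used to collapse compound ClinVar strings (higher = more severe).
CLINVAR_SEVERITY = {
    "pathogenic": 6,
    "likely_pathogenic": 5,
    "uncertain": 4,
    "likely_benign": 3,
    "benign": 2,
    "not_provided": 1,
    "absent": 0,
}

#: Default minor-allele-frequency sources checked by the rarity filter.
MAF_SOURCES = ("thousand_genomes", "exac_nfe_nontcga", "local")


VariantKey = tuple  # (chrom, pos, ref, alt)


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    return (str(chrom), int(pos), str(ref), str(alt))


@dataclass
class AnnotatedVariant:
    """A single variant with the annotations the cascade and screens consume.

    ``predictor_calls`` always carries exactly the ten tools of
    :data:`PREDICTOR_TOOLS`; tools the annotation source did not score are
    ``"missing"``.  ``clinvar`` holds the collapsed (most-severe) category and
    ``clinvar_raw`` the original string for reporting.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str
    consequence: str
    maf_by_source: dict = field(default_factory=dict)
    cadd_phred: float | None = None
    gerp: float | None = None
    phastcons: float | None = None
    phylop: float | None = None
    predictor_calls: dict = field(default_factory=dict)
    intolerance_ranks: dict = field(default_factory=dict)
    clinvar: str = "absent"
    clinvar_raw: str | None = None
    rsid: str | None = None

    def __post_init__(self) -> None:
        self.pos = int(self.pos)
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(
                f"unknown consequence {self.consequence!r}; expected one of {sorted(CONSEQUENCES)}"
            )
        for source, maf in self.maf_by_source.items():
            if maf is not None and not (0.0 <= maf <= 1.0):
                raise ValidationError(f"MAF for source {source!r} out of [0,1]: {maf}")
        # Normalise predictor calls to exactly the ten canonical tools.
        calls = {tool: "missing" for tool in PREDICTOR_TOOLS}
        for tool, call in self.predictor_calls.items():
            if tool not in calls:
                raise ValidationError(f"unknown predictor tool {tool!r}")
            if call not in PREDICTOR_CALLS:
                raise ValidationError(f"invalid predictor call {call!r} for {tool}")
            calls[tool] = call
        self.predictor_calls = calls
        if self.clinvar not in CLINVAR_SEVERITY:
            raise ValidationError(f"unknown clinvar category {self.clinvar!r}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError(f"cadd_phred must be >= 0, got {self.cadd_phred}")

    @property
    def key(self) -> VariantKey:
        return variant_key(self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_lof(self) -> bool:
        return self.consequence in LOF_CONSEQUENCES


@dataclass(frozen=True)
class SiteCounts:
    """Reference-population counts for one site: AC, Hom and AN.

    The invariants encode consistency of the triple: AN is a count of
    chromosomes (even), every homozygote contributes two alternate alleles
    (``2*hom <= ac``) and there cannot be more alternate alleles than
    chromosomes.  The number of carriers is ``ac - hom`` out of ``an/2``
    individuals.
    """

    variant_key: VariantKey
    ac: int
    hom: int
    an: int

    def __post_init__(self) -> None:
        for violation in self.violations():
            raise ValidationError(violation)

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty if valid)."""
        out = []
        if self.an <= 0:
            out.append(f"AN must be > 0, got {self.an}")
        elif self.an % 2 != 0:
            out.append(f"AN must be even (chromosome count), got {self.an}")
        if self.ac < 0:
            out.append(f"AC must be >= 0, got {self.ac}")
        if self.hom < 0:
            out.append(f"Hom must be >= 0, got {self.hom}")
        if self.ac > self.an:
            out.append(f"AC ({self.ac}) exceeds AN ({self.an})")
        if 2 * self.hom > self.ac:
            out.append(f"2*Hom ({2 * self.hom}) exceeds AC ({self.ac})")
        return out

    @property
    def carriers(self) -> int:
        """Number of individuals carrying at least one alternate allele."""
        return self.ac - self.hom


@dataclass
class RiskSNP:
    """One GWAS risk SNP with the metadata the exclusion criteria inspect."""

    rsid: str
    cancer_type: str
    risk_allele: str | None = None
    maf: float | None = None
    or_published: float | None = None
    subtype_specific: bool = False
    in_thousand_genomes: bool = True
    chrom: str | None = None
    pos: int | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.cancer_type not in {"BC", "CRC", "PC"}:
            raise ValidationError(f"cancer_type must be BC/CRC/PC, got {self.cancer_type!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValidationError(f"MAF out of [0,1]: {self.maf}")


class GenotypeMatrix:
    """Individuals x variants dosage table.

    Dosages are stored as float64 with values in {0, 1, 2} and ``NaN`` for
    missing calls; columns are keyed either by ``(chrom,pos,ref,alt)`` tuples
    or by rsID strings, whichever the pipeline stage joins on.
    """

    def __init__(
        self,
        individual_ids: Sequence[str],
        variant_keys: Sequence,
        dosages: np.ndarray,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(individual_ids), len(variant_keys)):
            raise ValidationError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(individual_ids)} individuals x {len(variant_keys)} variants"
            )
        observed = dosages[~np.isnan(dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))][:5]
            raise ValidationError(f"dosages must be in {{0,1,2,missing}}; found {bad}")
        if len(set(individual_ids)) != len(individual_ids):
            raise ValidationError("duplicate individual ids")
        if len(set(map(tuple, map(lambda k: k if isinstance(k, tuple) else (k,), variant_keys)))) != len(
            variant_keys
        ):
            raise ValidationError("duplicate variant keys")
        self.individual_ids = list(individual_ids)
        self.variant_keys = list(variant_keys)
        self.dosages = dosages

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def column(self, key) -> np.ndarray:
        return self.dosages[:, self.variant_keys.index(key)]

    def subset_variants(self, keys: Iterable) -> "GenotypeMatrix":
        keys = list(keys)
        idx = [self.variant_keys.index(k) for k in keys]
        return GenotypeMatrix(self.individual_ids, keys, self.dosages[:, idx])

    def to_frame(self) -> pd.DataFrame:
        cols = [_key_label(k) for k in self.variant_keys]
        return pd.DataFrame(self.dosages, index=self.individual_ids, columns=cols)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.variant_keys == other.variant_keys
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_individuals} individuals x {self.n_variants} variants)"


def _key_label(key) -> str:
    if isinstance(key, tuple):
        return ":".join(str(p) for p in key)
    return str(key)


def _key_from_label(label: str):
    parts = label.split(":")
    if len(parts) == 4 and parts[1].isdigit():
        return variant_key(*parts)
    return label


@dataclass
class QuartileSummary:
    """A 2 x 4 cohort-by-quartile summary with per-quartile ORs and the trend p.

    Quartile 1 is the reference stratum: its OR is fixed at 1.00 and its CI
    and p are undefined.
    """

    cutpoints: tuple
    labels: list
    reference_counts: list
    cohort_counts: list
    odds_ratios: list
    ci_low: list
    ci_high: list
    p_values: list
    trend_slope: float | None = None
    trend_p: float | None = None

    def __post_init__(self) -> None:
        if not (
            len(self.labels)
            == len(self.reference_counts)
            == len(self.cohort_counts)
            == len(self.odds_ratios)
            == 4
        ):
            raise ValidationError("quartile summary must have exactly 4 strata")
        if not (np.isclose(self.odds_ratios[0], 1.0)):
            raise ValidationError("quartile 1 OR must be fixed at 1.00")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "risk_alleles": self.labels,
                "reference_n": self.reference_counts,
                "cohort_n": self.cohort_counts,
                "or": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )


@dataclass
class CarrierResult:
    """Carrier-probability comparison for one gene-list x consequence stratum."""

    k: int
    p_cohort: float
    p_reference: float
    or_value: float | None
    ci_low: float | None
    ci_high: float | None
    n_boot: int
    seed: int | None
    flags: tuple = ()

    def __post_init__(self) -> None:
        for name in ("p_cohort", "p_reference"):
            p = getattr(self, name)
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} out of [0,1]: {p}")
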