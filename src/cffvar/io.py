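"""Readers and writers for the formats the pipeline touches.

Cohort genotypes arrive as VCF 4.x (read through cyvcf2, multi-allelic
records split into bi-allelic entries); everything else is tab-separated
text with a header row: annotation tables, reference site-count (AC/Hom/AN)
exports, risk-SNP lists and dosage matrices.  All report tables are written
back as TSV.

Predictor calls are normalised through a per-tool synonym map (``D`` means
deleterious for SIFT but ``P`` means polymorphism for MutationTaster and
possibly-damaging for PolyPhen-2, so the map is keyed by tool).  Compound
ClinVar strings such as ``"Likely benign/US"`` collapse to the most severe
listed category; the raw string is retained for reports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    CLINVAR_SEVERITY,
    CONSEQUENCES,
    MAF_SOURCES,
    PREDICTOR_TOOLS,
    AnnotatedVariant,
    GenotypeMatrix,
    ParseError,
    RiskSNP,
    SiteCounts,
    ValidationError,
    variant_key,
    _key_from_label,
    _key_label,
)

__all__ = [
    "read_cohort_vcf",
    "write_cohort_vcf",
    "read_site_counts",
    "write_site_counts",
    "read_annotations",
    "write_annotations",
    "read_risk_snps",
    "write_risk_snps",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "normalize_predictor_call",
    "normalize_clinvar",
]

# ---------------------------------------------------------------------------
# predictor-call normalisation

_COMMON_MISSING = {"", ".", "na", "nan", "none", "missing", "u", "unknown"}

#: Per-tool code synonyms.  Codes follow the dbNSFP conventions: SIFT D/T,
#: PolyPhen-2 D(probably)/P(possibly)/B(benign), LRT D/N/U, MutationTaster
#: A(disease causing automatic)/D/N/P(polymorphism), MutationAssessor
#: H/M(functional)/L/N, FATHMM D/T, MetaSVM & MetaLR D/T, PROVEAN D/N.
TOOL_CODE_MAP: dict = {
    "sift": {"d": "deleterious", "t": "tolerated"},
    "polyphen2_hdiv": {"d": "deleterious", "p": "deleterious", "b": "tolerated"},
    "polyphen2_hvar": {"d": "deleterious", "p": "deleterious", "b": "tolerated"},
    "lrt": {"d": "deleterious", "n": "tolerated"},
    "mutation_taster": {"a": "deleterious", "d": "deleterious", "n": "tolerated", "p": "tolerated"},
    "mutation_assessor": {"h": "deleterious", "m": "deleterious", "l": "tolerated", "n": "tolerated"},
    "fathmm": {"d": "deleterious", "t": "tolerated"},
    "metasvm": {"d": "deleterious", "t": "tolerated"},
    "metalr": {"d": "deleterious", "t": "tolerated"},
    "provean": {"d": "deleterious", "n": "tolerated"},
}

#: Column headers used in annotation TSVs for the ten tools.
TOOL_COLUMNS = {
    "sift": "SIFT",
    "polyphen2_hdiv": "PolyPhen2_HDIV",
    "polyphen2_hvar": "PolyPhen2_HVAR",
    "lrt": "LRT",
    "mutation_taster": "MutationTaster",
    "mutation_assessor": "MutationAssessor",
    "fathmm": "FATHMM",
    "metasvm": "MetaSVM",
    "metalr": "MetaLR",
    "provean": "PROVEAN",
}


def normalize_predictor_call(tool: str, raw) -> str:
    """Map a raw predictor code to {deleterious, tolerated, missing}.

    Raises :class:`ParseError` naming the tool and offending value for codes
    outside the documented synonym map.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "missing"
    text = str(raw).strip().lower()
    if text in _COMMON_MISSING:
        return "missing"
    if text in ("deleterious", "tolerated"):
        return text
    try:
        return TOOL_CODE_MAP[tool][text]
    except KeyError:
        raise ParseError(f"unknown predictor code {raw!r} in column {TOOL_COLUMNS.get(tool, tool)}")


_CLINVAR_TOKENS = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "likely_pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "uncertain significance": "uncertain",
    "uncertain_significance": "uncertain",
    "uncertain": "uncertain",
    "us": "uncertain",
    "vus": "uncertain",
    "likely benign": "likely_benign",
    "likely_benign": "likely_benign",
    "benign": "benign",
    "not provided": "not_provided",
    "not_provided": "not_provided",
    "conflicting": "uncertain",
    "-": "absent",
    ".": "absent",
    "": "absent",
    "absent": "absent",
}


def normalize_clinvar(raw) -> tuple[str, str | None]:
    """Collapse a (possibly compound) ClinVar string to one category.

    Returns ``(category, raw_string)``.  Compound values separated by ``/``,
    ``,`` or ``;`` map to the most severe listed category.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "absent", None
    text = str(raw).strip()
    if text.lower() in ("", ".", "-", "nan"):
        return "absent", text or None
    parts = [p.strip().lower() for chunk in text.split("/") for p in chunk.split(",")]
    parts = [q.strip() for p in parts for q in p.split(";") if q.strip()]
    cats = []
    for part in parts:
        if part not in _CLINVAR_TOKENS:
            raise ParseError(f"unknown ClinVar significance token {part!r} in {raw!r}")
        cats.append(_CLINVAR_TOKENS[part])
    if not cats:
        return "absent", text
    best = max(cats, key=lambda c: CLINVAR_SEVERITY[c])
    return best, text


# ---------------------------------------------------------------------------
# VCF

def read_cohort_vcf(path: str) -> tuple[GenotypeMatrix, list[AnnotatedVariant]]:
    """Read a cohort VCF into a dosage matrix plus variant skeletons.

    Dosage is the count of the alternate allele in the genotype; any missing
    allele makes the call missing.  Multi-allelic records are split into one
    bi-allelic entry per alternate allele.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as err:  # noqa: BLE001 - htslib raises bare exceptions
        raise ParseError(f"{path}: {_diagnose_vcf(path)}") from err
    samples = list(vcf.samples)
    keys: list = []
    skeletons: list[AnnotatedVariant] = []
    columns: list[np.ndarray] = []
    try:
        for record in vcf:
            genotypes = record.genotypes  # [[a0, a1, phased], ...]
            for alt_idx, alt in enumerate(record.ALT, start=1):
                dosage = np.full(len(samples), np.nan)
                for i, gt in enumerate(genotypes):
                    alleles = gt[:-1]
                    if any(a < 0 for a in alleles):
                        continue
                    dosage[i] = sum(1 for a in alleles if a == alt_idx)
                key = variant_key(record.CHROM, record.POS, record.REF, alt)
                keys.append(key)
                columns.append(dosage)
                skeletons.append(
                    AnnotatedVariant(
                        chrom=str(record.CHROM),
                        pos=record.POS,
                        ref_allele=record.REF,
                        alt_allele=alt,
                        gene="",
                        consequence="other",
                        rsid=record.ID,
                    )
                )
    except Exception as err:  # noqa: BLE001
        raise ParseError(f"{path}: {_diagnose_vcf(path)}") from err
    dosages = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, keys, dosages), skeletons


def _diagnose_vcf(path: str) -> str:
    """Best-effort localisation of the first malformed VCF data line."""
    try:
        with open(path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 8:
                    return f"malformed VCF data line {lineno}: expected >= 8 fields, found {len(fields)}"
                if not fields[1].isdigit():
                    return f"malformed VCF data line {lineno}: POS {fields[1]!r} is not an integer"
    except OSError as err:
        return f"unreadable: {err}"
    return "malformed VCF (htslib parse failure)"


def write_cohort_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a minimal GT-only VCF 4.2 for a matrix keyed by variant tuples."""
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = []
        for key in matrix.variant_keys:
            if key[0] not in chroms:
                chroms.append(key[0])
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individual_ids)
            + "\n"
        )
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, key in enumerate(matrix.variant_keys):
            chrom, pos, ref, alt = key
            calls = [
                "./." if np.isnan(d) else gt_codes[d] for d in matrix.dosages[:, j]
            ]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# site-count tables (AC / Hom / AN)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "AC", "Hom", "AN"]


def read_site_counts(path: str, strict: bool = False):
    """Read a reference site-count TSV into validated :class:`SiteCounts` rows.

    Returns ``(accepted, rejections)`` where ``accepted`` is a list of
    SiteCounts and ``rejections`` a DataFrame with one row per rejected input
    row and a ``violations`` column listing every failed invariant.  With
    ``strict=True`` any rejection raises :class:`ValidationError` instead.
    Validation is total: ``len(accepted) + len(rejections)`` equals the input
    row count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    accepted: list[SiteCounts] = []
    rejected: list[dict] = []
    for row in df.itertuples(index=True):
        probe = object.__new__(SiteCounts)
        object.__setattr__(probe, "variant_key", variant_key(row.chrom, row.pos, row.ref, row.alt))
        object.__setattr__(probe, "ac", int(row.AC))
        object.__setattr__(probe, "hom", int(row.Hom))
        object.__setattr__(probe, "an", int(row.AN))
        violations = probe.violations()
        if violations:
            rejected.append(
                {
                    "row": row.Index,
                    "chrom": row.chrom,
                    "pos": row.pos,
                    "ref": row.ref,
                    "alt": row.alt,
                    "violations": "; ".join(violations),
                }
            )
        else:
            accepted.append(probe)
    rejections = pd.DataFrame(rejected, columns=["row", "chrom", "pos", "ref", "alt", "violations"])
    if strict and len(rejections):
        raise ValidationError(
            f"{path}: {len(rejections)} invalid site-count rows; first: "
            f"{rejections.iloc[0]['violations']}"
        )
    return accepted, rejections


def write_site_counts(sites, path: str, clinvar: dict | None = None, genes: dict | None = None) -> None:
    """Write SiteCounts (optionally with gene / ClinVar columns) as TSV."""
    rows = []
    for s in sites:
        chrom, pos, ref, alt = s.variant_key
        row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "AC": s.ac, "Hom": s.hom, "AN": s.an}
        if genes is not None:
            row["gene"] = genes.get(s.variant_key, "")
        if clinvar is not None:
            row["clinvar"] = clinvar.get(s.variant_key, "absent")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def site_counts_frame(sites) -> pd.DataFrame:
    rows = [
        {"chrom": s.variant_key[0], "pos": s.variant_key[1], "ref": s.variant_key[2],
         "alt": s.variant_key[3], "AC": s.ac, "Hom": s.hom, "AN": s.an}
        for s in sites
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "AC", "Hom", "AN"])


# ---------------------------------------------------------------------------
# annotation tables

MAF_COLUMNS = {
    "thousand_genomes": "maf_thousand_genomes",
    "exac_nfe_nontcga": "maf_exac_nfe_nontcga",
    "local": "maf_local",
}
INTOLERANCE_COLUMNS = {
    "esp6500": "intol_esp6500",
    "exac": "intol_exac",
    "local": "intol_local",
    "missense_z": "missense_z",
}
_SCORE_COLUMNS = {"cadd_phred": "cadd_phred", "gerp": "gerp", "phastcons": "phastcons", "phylop": "phylop"}


def _opt_float(value):
    if value is None:
        return None
    if isinstance(value, str):
        if value.strip() in ("", ".", "-", "NA"):
            return None
        return float(value)
    if isinstance(value, float) and np.isnan(value):
        return None
    return float(value)


def read_annotations(path: str) -> list[AnnotatedVariant]:
    """Read an annotation TSV into :class:`AnnotatedVariant` records.

    Required columns: chrom, pos, ref, alt, gene, consequence.  Optional:
    rsid, the three MAF columns, cadd_phred, gerp, phastcons, phylop, the ten
    predictor columns (codes per :data:`TOOL_CODE_MAP`), the intolerance
    columns and clinvar.  Empty cells mean "missing".
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False, na_values=[])
    required = ["chrom", "pos", "ref", "alt", "gene", "consequence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    variants = []
    for row in df.to_dict("records"):
        consequence = str(row["consequence"]).strip()
        if consequence not in CONSEQUENCES:
            raise ParseError(f"{path}: unknown consequence {consequence!r}")
        mafs = {}
        for source, col in MAF_COLUMNS.items():
            if col in df.columns:
                value = _opt_float(row[col])
                if value is not None:
                    mafs[source] = value
        calls = {}
        for tool, col in TOOL_COLUMNS.items():
            if col in df.columns:
                calls[tool] = normalize_predictor_call(tool, row[col])
        intolerance = {}
        for name, col in INTOLERANCE_COLUMNS.items():
            if col in df.columns:
                value = _opt_float(row[col])
                if value is not None:
                    intolerance[name] = value
        clinvar_cat, clinvar_raw = normalize_clinvar(row.get("clinvar"))
        rsid = str(row.get("rsid", "")).strip() or None
        if rsid in (".", "-"):
            rsid = None
        variants.append(
            AnnotatedVariant(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref_allele=str(row["ref"]),
                alt_allele=str(row["alt"]),
                gene=str(row["gene"]),
                consequence=consequence,
                maf_by_source=mafs,
                cadd_phred=_opt_float(row.get("cadd_phred")),
                gerp=_opt_float(row.get("gerp")),
                phastcons=_opt_float(row.get("phastcons")),
                phylop=_opt_float(row.get("phylop")),
                predictor_calls=calls,
                intolerance_ranks=intolerance,
                clinvar=clinvar_cat,
                clinvar_raw=clinvar_raw,
                rsid=rsid,
            )
        )
    return variants


# Canonical per-tool output codes (each tool has its own vocabulary).
_CALL_CODES = {
    tool: {
        "deleterious": "H" if tool == "mutation_assessor" else "D",
        "tolerated": {
            "polyphen2_hdiv": "B",
            "polyphen2_hvar": "B",
            "lrt": "N",
            "mutation_taster": "N",
            "mutation_assessor": "N",
            "provean": "N",
        }.get(tool, "T"),
        "missing": ".",
    }
    for tool in PREDICTOR_TOOLS
}


def write_annotations(variants, path: str) -> None:
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "gene": v.gene,
            "consequence": v.consequence,
            "rsid": v.rsid or ".",
        }
        for source, col in MAF_COLUMNS.items():
            row[col] = v.maf_by_source.get(source, "")
        for attr, col in _SCORE_COLUMNS.items():
            value = getattr(v, attr)
            row[col] = "" if value is None else value
        for tool, col in TOOL_COLUMNS.items():
            row[col] = _CALL_CODES[tool][v.predictor_calls[tool]]
        for name, col in INTOLERANCE_COLUMNS.items():
            value = v.intolerance_ranks.get(name)
            row[col] = "" if value is None else value
        row["clinvar"] = v.clinvar_raw if v.clinvar_raw is not None else v.clinvar
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# risk-SNP lists

RISK_SNP_COLUMNS = [
    "rsid", "cancer_type", "risk_allele", "maf", "or_published",
    "subtype_specific", "in_thousand_genomes", "chrom", "pos", "gene",
]


def read_risk_snps(path: str) -> list[RiskSNP]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False, na_values=[])
    missing = [c for c in ("rsid", "cancer_type") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    snps = []
    for row in df.to_dict("records"):
        risk_allele = str(row.get("risk_allele", "")).strip()
        snps.append(
            RiskSNP(
                rsid=str(row["rsid"]),
                cancer_type=str(row["cancer_type"]),
                risk_allele=risk_allele if risk_allele not in ("", ".", "-") else None,
                maf=_opt_float(row.get("maf")),
                or_published=_opt_float(row.get("or_published")),
                subtype_specific=_parse_bool(row.get("subtype_specific", False)),
                in_thousand_genomes=_parse_bool(row.get("in_thousand_genomes", True)),
                chrom=str(row["chrom"]) if str(row.get("chrom", "")).strip() else None,
                pos=int(row["pos"]) if str(row.get("pos", "")).strip() else None,
                gene=str(row["gene"]) if str(row.get("gene", "")).strip() else None,
            )
        )
    return snps


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("1", "true", "yes", "y"):
        return True
    if text in ("0", "false", "no", "n", ""):
        return False
    raise ParseError(f"cannot interpret {value!r} as a boolean")


def write_risk_snps(snps, path: str) -> None:
    rows = []
    for s in snps:
        rows.append(
            {
                "rsid": s.rsid,
                "cancer_type": s.cancer_type,
                "risk_allele": s.risk_allele or ".",
                "maf": "" if s.maf is None else s.maf,
                "or_published": "" if s.or_published is None else s.or_published,
                "subtype_specific": int(s.subtype_specific),
                "in_thousand_genomes": int(s.in_thousand_genomes),
                "chrom": s.chrom or "",
                "pos": "" if s.pos is None else s.pos,
                "gene": s.gene or "",
            }
        )
    pd.DataFrame(rows, columns=RISK_SNP_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dosage matrices as TSV (individual rows, variant columns)

def write_matrix_tsv(matrix: GenotypeMatrix, path: str) -> None:
    frame = matrix.to_frame()
    frame.index.name = "individual"
    out = frame.map(lambda d: "." if np.isnan(d) else str(int(d)))
    out.to_csv(path, sep="\t")


def read_matrix_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dosages = df.replace(".", np.nan).astype(float).to_numpy()
    keys = [_key_from_label(c) for c in df.columns]
    return GenotypeMatrix([str(i) for i in df.index], keys, dosages)
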