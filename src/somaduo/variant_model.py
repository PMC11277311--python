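"""Domain types and file I/O for somatic variant calls, annotations, and gene panels.

The pipeline starts from per-sample somatic VCFs produced by an upstream
caller (Mutect2-style): FILTER labels other than PASS are treated as caller
hard-filter flags, and the variant allele fraction (VAF) is always recomputed
from the allelic depths so that depth, alt-read count and VAF thresholds stay
internally consistent. Multiallelic sites are split into one record per ALT
allele; indel normalisation/left-alignment is assumed done upstream.

Annotations (population frequencies, sequence ontology, in-silico predictor
verdicts, clinical classification, cancer-mutation-catalogue evidence, gene
role) arrive as a flat TSV keyed by (chrom, pos, ref, alt) and are joined
onto records allele-exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "MISSING",
    "SeqOntology",
    "Effect",
    "Verdict",
    "ClinicalClass",
    "GeneRole",
    "PREDICTORS",
    "AnnotationBundle",
    "VariantRecord",
    "GenePanel",
    "VariantKey",
    "read_vcf",
    "read_annotations",
    "attach_annotations",
    "read_gene_panel",
    "write_annotations",
    "write_variant_table",
]

#: Sentinel for absent annotation values; distinct from 0 for frequency fields.
MISSING = None

VariantKey = tuple[str, int, str, str]


class SeqOntology(str, enum.Enum):
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    SPLICE_VARIANT = "splice_variant"
    STOP_GAINED = "stop_gained"
    INITIATOR_CODON = "initiator_codon"
    INTRAGENIC = "intragenic"
    INTRON = "intron"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Effect(str, enum.Enum):
    LOF = "LoF"
    MISSENSE = "missense"
    OTHER = "other"
    UNKNOWN = "unknown"
    NONE = "none"


class Verdict(str, enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"


class ClinicalClass(str, enum.Enum):
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS_WEAK_BENIGN = "vus_weak_benign"
    OTHER = "other"


class GeneRole(str, enum.Enum):
    ONCOGENE = "oncogene"
    TUMOR_SUPPRESSOR = "tumor_suppressor"
    FUSION = "fusion"
    NONE = "none"


#: Canonical in-silico predictor names, in voting order.
PREDICTORS = (
    "SIFT",
    "PolyPhen2-HVAR",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "FATHMM-MKL",
)

# TSV column <-> canonical predictor name
_PREDICTOR_COLUMNS = {
    "sift": "SIFT",
    "polyphen2_hvar": "PolyPhen2-HVAR",
    "mutation_taster": "MutationTaster",
    "mutation_assessor": "MutationAssessor",
    "fathmm": "FATHMM",
    "fathmm_mkl": "FATHMM-MKL",
}

ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "af_1kg",
    "af_gnomad_exome",
    "maf_esp",
    "dbsnp_common",
    "seq_ontology",
    "effect",
    *_PREDICTOR_COLUMNS,
    "clinical_class",
    "cosmic_ids",
    "cosmic_count",
    "gene",
    "gene_role",
    "hgvs_c",
    "hgvs_p",
)


@dataclass(frozen=True)
class AnnotationBundle:
    """Per-variant annotation evidence.

    Frequency fields use ``None`` (MISSING) when the variant is absent from
    the population resource — distinct from an observed frequency of 0.
    ``cosmic_count`` is the catalogue *sample* count (how many tumors carry
    the mutation), independent of the length of ``cosmic_ids``.
    """

    af_1kg: float | None = MISSING
    af_gnomad_exome: float | None = MISSING
    maf_esp: float | None = MISSING
    dbsnp_common: bool = False
    seq_ontology: SeqOntology = SeqOntology.OTHER
    effect: Effect = Effect.NONE
    predictor_verdicts: Mapping[str, Verdict | None] = field(
        default_factory=lambda: {p: MISSING for p in PREDICTORS}
    )
    clinical_class: ClinicalClass | None = MISSING
    cosmic_ids: tuple[str, ...] = ()
    cosmic_count: int = 0
    gene: str = ""
    gene_role: GeneRole = GeneRole.NONE
    hgvs_c: str = ""
    hgvs_p: str = ""

    def __post_init__(self) -> None:
        for name in ("af_1kg", "af_gnomad_exome", "maf_esp"):
            v = getattr(self, name)
            if v is not MISSING and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.cosmic_count < 0:
            raise ValueError("cosmic_count must be >= 0")


#: Bundle attached to records with no matching annotation row.
DEFAULT_BUNDLE = AnnotationBundle()


@dataclass(frozen=True)
class VariantRecord:
    """One called somatic variant in one sample (single ALT allele).

    ``vaf`` is recomputed as ``alt_depth / total_depth`` and never trusted
    from the input. Coordinates are 1-based (VCF convention).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    total_depth: int
    alt_depth: int
    caller_flags: frozenset[str] = frozenset()
    annotations: AnnotationBundle = DEFAULT_BUNDLE

    def __post_init__(self) -> None:
        if not (0 <= self.alt_depth <= self.total_depth):
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, total_depth={self.total_depth}] "
                f"at {self.chrom}:{self.pos}"
            )
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.total_depth if self.total_depth > 0 else 0.0

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols, case-normalized to upper case."""

    symbols: frozenset[str]
    name: str = "panel"

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("gene panel is empty")
        object.__setattr__(
            self, "symbols", frozenset(s.strip().upper() for s in self.symbols)
        )

    def __contains__(self, gene: str) -> bool:
        return gene.strip().upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, sample_id: str) -> list[VariantRecord]:
    """Read a single-sample VCF into VariantRecords, one per (site, ALT allele).

    FILTER labels other than PASS are copied into ``caller_flags``.
    Multiallelic sites are split; the per-allele alt depth comes from AD.
    Missing DP or AD FORMAT fields are a hard error naming the offending site.
    """
    path = str(path)
    records: list[VariantRecord] = []
    vcf = VCF(path)
    try:
        for v in vcf:
            where = f"{path}: {v.CHROM}:{v.POS} {v.REF}>{','.join(v.ALT or ['.'])}"
            dp = v.format("DP")
            ad = v.format("AD")
            if dp is None or ad is None:
                raise ValueError(f"missing FORMAT DP or AD at {where}")
            total_depth = int(dp[0][0])
            ad_row = [int(x) for x in ad[0]]
            if len(ad_row) != 1 + len(v.ALT):
                raise ValueError(
                    f"AD has {len(ad_row)} entries for {len(v.ALT)} ALT alleles at {where}"
                )
            flags = frozenset(
                f for f in (v.FILTER or "").split(";") if f and f != "PASS"
            )
            for i, alt in enumerate(v.ALT):
                records.append(
                    VariantRecord(
                        sample_id=sample_id,
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        total_depth=total_depth,
                        alt_depth=min(ad_row[1 + i], total_depth),
                        caller_flags=flags,
                    )
                )
    finally:
        vcf.close()
    return records


def _parse_fraction(cell: str, column: str, where: str) -> float | None:
    if cell == "":
        return MISSING
    try:
        value = float(cell)
    except ValueError as exc:
        raise ValueError(f"malformed fraction {cell!r} in column {column} at {where}") from exc
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"fraction {value} outside [0, 1] in column {column} at {where}")
    return value


def _parse_enum(cell: str, enum_cls, column: str, where: str, default):
    if cell == "":
        return default
    try:
        return enum_cls(cell)
    except ValueError as exc:
        raise ValueError(
            f"unknown {column} value {cell!r} at {where}; "
            f"expected one of {[e.value for e in enum_cls]}"
        ) from exc


def _parse_bool(cell: str) -> bool:
    return cell.strip().lower() in {"true", "1", "yes"}


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotationBundle]:
    """Read the annotation TSV into a map from (chrom, pos, ref, alt) to bundle.

    Empty cells mean MISSING; unknown enum strings and duplicate keys are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: annotation table lacks columns {sorted(missing_cols)}")
    bundles: dict[VariantKey, AnnotationBundle] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        key: VariantKey = (
            str(row["chrom"]),
            int(row["pos"]),
            str(row["ref"]).upper(),
            str(row["alt"]).upper(),
        )
        where = f"{path} line {idx}"
        if key in bundles:
            raise ValueError(f"duplicate annotation key {key} at {where}")
        verdicts = {
            _PREDICTOR_COLUMNS[col]: _parse_enum(row[col], Verdict, col, where, MISSING)
            for col in _PREDICTOR_COLUMNS
        }
        cosmic_ids = tuple(s for s in str(row["cosmic_ids"]).split(",") if s)
        bundles[key] = AnnotationBundle(
            af_1kg=_parse_fraction(row["af_1kg"], "af_1kg", where),
            af_gnomad_exome=_parse_fraction(row["af_gnomad_exome"], "af_gnomad_exome", where),
            maf_esp=_parse_fraction(row["maf_esp"], "maf_esp", where),
            dbsnp_common=_parse_bool(row["dbsnp_common"]),
            seq_ontology=_parse_enum(
                row["seq_ontology"], SeqOntology, "seq_ontology", where, SeqOntology.OTHER
            ),
            effect=_parse_enum(row["effect"], Effect, "effect", where, Effect.NONE),
            predictor_verdicts=verdicts,
            clinical_class=_parse_enum(
                row["clinical_class"], ClinicalClass, "clinical_class", where, MISSING
            ),
            cosmic_ids=cosmic_ids,
            cosmic_count=int(row["cosmic_count"]) if row["cosmic_count"] else 0,
            gene=str(row["gene"]).strip().upper(),
            gene_role=_parse_enum(row["gene_role"], GeneRole, "gene_role", where, GeneRole.NONE),
            hgvs_c=str(row["hgvs_c"]),
            hgvs_p=str(row["hgvs_p"]),
        )
    return bundles


def write_annotations(
    bundles: Mapping[VariantKey, AnnotationBundle], path: str | Path
) -> None:
    """Write bundles back to the TSV dialect `read_annotations` consumes."""
    rows = []
    for (chrom, pos, ref, alt), b in bundles.items():
        row = {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "af_1kg": "" if b.af_1kg is MISSING else repr(b.af_1kg),
            "af_gnomad_exome": "" if b.af_gnomad_exome is MISSING else repr(b.af_gnomad_exome),
            "maf_esp": "" if b.maf_esp is MISSING else repr(b.maf_esp),
            "dbsnp_common": "true" if b.dbsnp_common else "false",
            "seq_ontology": b.seq_ontology.value,
            "effect": b.effect.value,
            "clinical_class": "" if b.clinical_class is MISSING else b.clinical_class.value,
            "cosmic_ids": ",".join(b.cosmic_ids),
            "cosmic_count": b.cosmic_count,
            "gene": b.gene,
            "gene_role": b.gene_role.value,
            "hgvs_c": b.hgvs_c,
            "hgvs_p": b.hgvs_p,
        }
        for col, name in _PREDICTOR_COLUMNS.items():
            verdict = b.predictor_verdicts.get(name, MISSING)
            row[col] = "" if verdict is MISSING else Verdict(verdict).value
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def attach_annotations(
    records: Iterable[VariantRecord],
    bundles: Mapping[VariantKey, AnnotationBundle],
    default_policy: AnnotationBundle = DEFAULT_BUNDLE,
) -> list[VariantRecord]:
    """Left-join bundles onto records by allele-exact key.

    Records without a matching bundle get ``default_policy``; the record set
    is never grown or shrunk.
    """
    return [
        replace(r, annotations=bundles.get(r.key, default_policy)) for r in records
    ]


def read_gene_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Read a plain-text gene list (one symbol per line, '#' comments allowed)."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.add(line.upper())
    if not symbols:
        raise ValueError(f"gene panel {path} contains no symbols")
    return GenePanel(symbols=frozenset(symbols), name=name or Path(path).stem)


def variant_table(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Flatten records (one row each) with all annotation fields as columns."""
    rows = []
    for r in records:
        b = r.annotations
        row = {
            "sample_id": r.sample_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "total_depth": r.total_depth,
            "alt_depth": r.alt_depth,
            "vaf": r.vaf,
            "caller_flags": ";".join(sorted(r.caller_flags)),
            "gene": b.gene,
            "gene_role": b.gene_role.value,
            "seq_ontology": b.seq_ontology.value,
            "effect": b.effect.value,
            "clinical_class": "" if b.clinical_class is MISSING else b.clinical_class.value,
            "af_1kg": b.af_1kg,
            "af_gnomad_exome": b.af_gnomad_exome,
            "maf_esp": b.maf_esp,
            "dbsnp_common": b.dbsnp_common,
            "cosmic_ids": ",".join(b.cosmic_ids),
            "cosmic_count": b.cosmic_count,
            "hgvs_c": b.hgvs_c,
            "hgvs_p": b.hgvs_p,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    variant_table(records).to_csv(path, sep="\t", index=False)
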