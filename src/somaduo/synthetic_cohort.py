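"""Synthetic paired primary/recurrent cohorts with planted ground truth.

The generator emulates the statistical structure the duo analysis assumes:

* trunk variants shared by both samples, with VAFs drawn around per-sample
  clonal centers (multi-component clonal structure);
* private variants confined to one sample;
* FFPE-style artifacts — low-VAF C>T calls carrying a caller hard-filter
  flag (strand bias / fragment), emulating formalin deamination damage;
* common germline polymorphisms present in both samples near VAF 0.5 with
  high population allele frequencies and dbSNP-common membership.

Depths are Poisson around a configurable mean chosen to match deep FFPE
exome coverage; alt depths are rounded from the drawn VAF so that depth,
alt count and VAF are mutually consistent. Planted driver annotations come
from a small in-repo catalogue of cancer genes (roles, ontologies,
catalogue recurrence counts and hand-computed expected oncogenicity
classes), so downstream reports resemble real gene-level summaries without
any external database.

``expected_counts`` is a deliberately independent oracle: it predicts every
per-level audit count and duo category tally by direct enumeration over the
planted truth, without touching the pipeline modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .filter_cascade import FilterConfig
from .duo_analysis import RescueConfig
from .variant_model import (
    MISSING,
    AnnotationBundle,
    ClinicalClass,
    Effect,
    GeneRole,
    PREDICTORS,
    SeqOntology,
    VariantKey,
    Verdict,
    write_annotations,
)

__all__ = [
    "CatalogueEntry",
    "DRIVER_CATALOGUE",
    "OFF_PANEL_GENES",
    "SimConfig",
    "TruthVariant",
    "SyntheticTruth",
    "DuoPaths",
    "simulate_duo",
    "expected_counts",
]


@dataclass(frozen=True)
class CatalogueEntry:
    """One plantable driver lesion with hand-computed expected score/class.

    ``expected_score`` is the manual summation of the default rubric points
    for this annotation profile (catalogue-recurrence tier, LoF-in-tumor-
    suppressor, missense predictor consensus, splice disruption, recurrent
    oncogene); it serves as an independent oracle for the classifier.
    """

    gene: str
    chrom: str
    start: int
    role: GeneRole
    ontology: SeqOntology
    effect: Effect
    cosmic_count: int
    damaging_votes: int
    expected_score: int
    expected_class: str  # "O" / "LO" / "VUS"


# Hand-scored against the default rubric:
#   recurrence: >=50 -> +4, 10..49 -> +2, 1..9 -> +1 (exclusive tiers)
#   LoF in tumor suppressor +4; missense with >=3 damaging votes +2;
#   splice variant +2; oncogene with count >=10 +2.
DRIVER_CATALOGUE: tuple[CatalogueEntry, ...] = (
    CatalogueEntry("TP53", "17", 7_571_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.MISSENSE, Effect.MISSENSE, 1044, 6, 6, "O"),
    CatalogueEntry("APC", "5", 112_100_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.FRAMESHIFT, Effect.LOF, 82, 4, 8, "O"),
    CatalogueEntry("EGFR", "7", 55_086_000, GeneRole.ONCOGENE, SeqOntology.MISSENSE, Effect.MISSENSE, 80, 5, 8, "O"),
    CatalogueEntry("RB1", "13", 48_877_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.SPLICE_VARIANT, Effect.LOF, 21, 3, 8, "O"),
    CatalogueEntry("KMT2D", "12", 49_412_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.FRAMESHIFT, Effect.LOF, 12, 2, 6, "O"),
    CatalogueEntry("SMARCA4", "19", 11_071_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.FRAMESHIFT, Effect.LOF, 8, 2, 5, "O"),
    CatalogueEntry("STK11", "19", 1_205_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.FRAMESHIFT, Effect.LOF, 2, 1, 5, "O"),
    CatalogueEntry("PTEN", "10", 89_623_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.MISSENSE, Effect.MISSENSE, 30, 4, 4, "LO"),
    CatalogueEntry("DNMT3A", "2", 25_455_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.MISSENSE, Effect.MISSENSE, 5, 3, 3, "LO"),
    CatalogueEntry("CREBBP", "16", 3_775_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.MISSENSE, Effect.MISSENSE, 4, 4, 3, "LO"),
    CatalogueEntry("NOTCH1", "9", 139_388_000, GeneRole.ONCOGENE, SeqOntology.SPLICE_VARIANT, Effect.OTHER, 2, 1, 3, "LO"),
    CatalogueEntry("HNF1A", "12", 121_416_000, GeneRole.ONCOGENE, SeqOntology.MISSENSE, Effect.MISSENSE, 2, 3, 3, "LO"),
    CatalogueEntry("RUNX1", "21", 36_160_000, GeneRole.FUSION, SeqOntology.FRAMESHIFT, Effect.LOF, 21, 2, 2, "VUS"),
    CatalogueEntry("PTPN11", "12", 112_856_000, GeneRole.ONCOGENE, SeqOntology.MISSENSE, Effect.MISSENSE, 3, 2, 1, "VUS"),
    CatalogueEntry("BAP1", "3", 52_435_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.MISSENSE, Effect.MISSENSE, 1, 1, 1, "VUS"),
    CatalogueEntry("VHL", "3", 10_183_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.MISSENSE, Effect.MISSENSE, 2, 2, 1, "VUS"),
    CatalogueEntry("BTK", "X", 100_604_000, GeneRole.ONCOGENE, SeqOntology.MISSENSE, Effect.MISSENSE, 1, 1, 1, "VUS"),
    CatalogueEntry("NF1", "17", 29_421_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.MISSENSE, Effect.MISSENSE, 6, 2, 1, "VUS"),
    CatalogueEntry("BRCA2", "13", 32_889_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.MISSENSE, Effect.MISSENSE, 9, 1, 1, "VUS"),
    CatalogueEntry("POLE", "12", 133_200_000, GeneRole.TUMOR_SUPPRESSOR, SeqOntology.MISSENSE, Effect.MISSENSE, 3, 2, 1, "VUS"),
)

#: Genes deliberately absent from the panel (their variants fail level 3).
OFF_PANEL_GENES: tuple[CatalogueEntry, ...] = (
    CatalogueEntry("TTN", "2", 179_390_000, GeneRole.NONE, SeqOntology.MISSENSE, Effect.MISSENSE, 2, 1, 1, "VUS"),
    CatalogueEntry("MUC16", "19", 8_959_000, GeneRole.NONE, SeqOntology.MISSENSE, Effect.MISSENSE, 1, 1, 1, "VUS"),
    CatalogueEntry("OBSCN", "1", 228_395_000, GeneRole.NONE, SeqOntology.MISSENSE, Effect.MISSENSE, 1, 2, 1, "VUS"),
)

#: Extra glioma panel padding (no variants planted on these).
_PANEL_PADDING = (
    "IDH1", "IDH2", "ATRX", "CIC", "FUBP1", "TERT", "CDKN2A", "CDK4", "MDM2",
    "PDGFRA", "PIK3CA", "PIK3R1", "MET", "MYC", "MYCN", "FGFR1", "FGFR3",
    "H3F3A", "HIST1H3B", "SETD2", "BRAF", "KRAS", "NRAS", "AKT1", "MTOR",
    "TSC1", "TSC2", "ARID1A", "ARID2", "PBRM1", "KDM6A", "GABRA6", "SMO",
    "PTCH1", "SUFU", "DDX3X", "KDR", "KIT", "MSH2", "MSH6",
)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped conditions for one simulated primary/recurrent duo."""

    seed: int = 0
    pair_id: str = "pair1"
    capture_mb: float = 42.0
    n_trunk: int = 8
    n_private_P: int = 6
    n_private_R: int = 9
    clone_vaf_centers_P: tuple[float, ...] = (0.45, 0.26)
    clone_vaf_centers_R: tuple[float, ...] = (0.48, 0.30)
    clone_sd: float = 0.03
    n_artifacts_P: int = 40
    n_artifacts_R: int = 50
    artifact_vaf_range: tuple[float, float] = (0.01, 0.10)
    n_polymorphisms: int = 15
    depth_mean: int = 180
    panel_fraction: float = 0.8
    n_rescuable_trunk: int = 1
    n_lost_trunk: int = 0
    driver_catalogue: tuple[CatalogueEntry, ...] = DRIVER_CATALOGUE

    def __post_init__(self) -> None:
        counts = (
            self.n_trunk, self.n_private_P, self.n_private_R,
            self.n_artifacts_P, self.n_artifacts_R, self.n_polymorphisms,
            self.n_rescuable_trunk, self.n_lost_trunk,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all simulation counts must be >= 0")
        if self.n_trunk > 0 and (
            not self.clone_vaf_centers_P or not self.clone_vaf_centers_R
        ):
            raise ValueError("clone VAF centers required when n_trunk > 0")
        for c in (*self.clone_vaf_centers_P, *self.clone_vaf_centers_R):
            if not (0.0 < c < 1.0):
                raise ValueError(f"clone VAF center {c} outside (0, 1)")
        if self.n_rescuable_trunk + self.n_lost_trunk > self.n_trunk:
            raise ValueError("rescuable + lost trunk variants exceed n_trunk")
        if not (0.0 <= self.panel_fraction <= 1.0):
            raise ValueError("panel_fraction must be in [0, 1]")


@dataclass
class TruthVariant:
    """Planted ground truth for one variant (both samples' raw evidence)."""

    key: VariantKey
    gene: str
    origin: str  # trunk | private_P | private_R | artifact | polymorphism
    in_panel: bool
    clone_P: int = -1
    clone_R: int = -1
    rescue_planted: bool = False  # trunk variant degraded in R but above rescue floor
    expected_class: str = ""
    annotations: AnnotationBundle = AnnotationBundle()
    # per-sample raw call evidence; None when absent from that sample's VCF
    evidence_P: tuple[int, int, frozenset[str]] | None = None  # (depth, alt, flags)
    evidence_R: tuple[int, int, frozenset[str]] | None = None

    def vaf(self, sample: str) -> float | None:
        ev = self.evidence_P if sample == "P" else self.evidence_R
        if ev is None:
            return None
        depth, alt, _ = ev
        return alt / depth if depth > 0 else 0.0


@dataclass
class SyntheticTruth:
    pair_id: str
    config: SimConfig
    variants: list[TruthVariant] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tv in self.variants:
            rows.append(
                {
                    "chrom": tv.key[0], "pos": tv.key[1], "ref": tv.key[2], "alt": tv.key[3],
                    "gene": tv.gene, "origin": tv.origin, "in_panel": tv.in_panel,
                    "clone_P": tv.clone_P, "clone_R": tv.clone_R,
                    "rescue_planted": tv.rescue_planted,
                    "expected_class": tv.expected_class,
                    "depth_P": tv.evidence_P[0] if tv.evidence_P else "",
                    "alt_P": tv.evidence_P[1] if tv.evidence_P else "",
                    "depth_R": tv.evidence_R[0] if tv.evidence_R else "",
                    "alt_R": tv.evidence_R[1] if tv.evidence_R else "",
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DuoPaths:
    vcf_p: Path
    vcf_r: Path
    annotations: Path
    panel: Path
    truth: Path


def _draw_depth(rng: np.random.Generator, mean: int) -> int:
    return max(int(rng.poisson(mean)), 30)


def _depth_alt_for_vaf(rng: np.random.Generator, vaf: float, depth_mean: int) -> tuple[int, int]:
    depth = _draw_depth(rng, depth_mean)
    alt = int(np.clip(round(vaf * depth), 1, depth))
    return depth, alt


def _unique_key(
    rng: np.random.Generator,
    entry: CatalogueEntry,
    used: set[VariantKey],
    ref: str | None = None,
    alt: str | None = None,
) -> VariantKey:
    for _ in range(1000):
        pos = int(entry.start + rng.integers(0, 50_000))
        r = ref or _BASES[rng.integers(4)]
        choices = [b for b in _BASES if b != r]
        a = alt or choices[rng.integers(3)]
        key = (entry.chrom, pos, r, a)
        if key not in used:
            used.add(key)
            return key
    raise RuntimeError("could not draw a unique variant key")


def _driver_bundle(rng: np.random.Generator, entry: CatalogueEntry) -> AnnotationBundle:
    verdicts = {
        p: (Verdict.DAMAGING if i < entry.damaging_votes else Verdict.TOLERATED)
        for i, p in enumerate(PREDICTORS)
    }
    cosmic_ids = (
        (f"COSM{int(rng.integers(10_000, 9_999_999))}",) if entry.cosmic_count >= 1 else ()
    )
    return AnnotationBundle(
        seq_ontology=entry.ontology,
        effect=entry.effect,
        predictor_verdicts=verdicts,
        clinical_class=ClinicalClass.OTHER,
        cosmic_ids=cosmic_ids,
        cosmic_count=entry.cosmic_count,
        gene=entry.gene,
        gene_role=entry.role,
        hgvs_c=f"c.{int(rng.integers(1, 5000))}N>N",
        hgvs_p=f"p.X{int(rng.integers(1, 1500))}X",
    )


def simulate_duo(config: SimConfig, out_dir: str | Path) -> tuple[DuoPaths, SyntheticTruth]:
    """Generate one duo: two VCFs, an annotation TSV, a panel file and truth.

    Fully reproducible: the same config (seed included) yields byte-identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    used: set[VariantKey] = set()
    truth = SyntheticTruth(pair_id=config.pair_id, config=config)

    def clone_vaf(centers: Sequence[float], idx: int) -> float:
        return float(np.clip(rng.normal(centers[idx], config.clone_sd), 0.02, 0.98))

    def plant_true(origin: str, n: int) -> list[TruthVariant]:
        planted = []
        for i in range(n):
            force_panel = origin == "trunk" and i < (config.n_rescuable_trunk + config.n_lost_trunk)
            in_panel = force_panel or bool(rng.random() < config.panel_fraction)
            pool = config.driver_catalogue if in_panel else OFF_PANEL_GENES
            entry = pool[int(rng.integers(len(pool)))]
            key = _unique_key(rng, entry, used)
            tv = TruthVariant(
                key=key,
                gene=entry.gene,
                origin=origin,
                in_panel=in_panel and entry.role != GeneRole.NONE,
                expected_class=entry.expected_class,
                annotations=_driver_bundle(rng, entry),
            )
            if origin in ("trunk", "private_P"):
                tv.clone_P = int(rng.integers(len(config.clone_vaf_centers_P)))
                vaf = clone_vaf(config.clone_vaf_centers_P, tv.clone_P)
                depth, alt = _depth_alt_for_vaf(rng, vaf, config.depth_mean)
                tv.evidence_P = (depth, alt, frozenset())
            if origin in ("trunk", "private_R"):
                tv.clone_R = int(rng.integers(len(config.clone_vaf_centers_R)))
                if origin == "trunk" and i < config.n_rescuable_trunk:
                    # degraded in R: below the level-1 VAF floor, above rescue floor
                    vaf = float(rng.uniform(0.06, 0.12))
                    tv.rescue_planted = True
                elif origin == "trunk" and i < config.n_rescuable_trunk + config.n_lost_trunk:
                    # lost in R: below even the rescue evidence floor
                    vaf = 0.01
                else:
                    vaf = clone_vaf(config.clone_vaf_centers_R, tv.clone_R)
                depth, alt = _depth_alt_for_vaf(rng, vaf, config.depth_mean)
                tv.evidence_R = (depth, alt, frozenset())
            planted.append(tv)
        return planted

    truth.variants += plant_true("trunk", config.n_trunk)
    truth.variants += plant_true("private_P", config.n_private_P)
    truth.variants += plant_true("private_R", config.n_private_R)

    # FFPE-style artifacts: low-VAF C>T with an excluded caller flag
    flag_pool = sorted(FilterConfig().excluded_caller_flags)
    for sample, n in (("P", config.n_artifacts_P), ("R", config.n_artifacts_R)):
        for _ in range(n):
            entry = config.driver_catalogue[int(rng.integers(len(config.driver_catalogue)))]
            key = _unique_key(rng, entry, used, ref="C", alt="T")
            vaf = float(rng.uniform(*config.artifact_vaf_range))
            depth, alt = _depth_alt_for_vaf(rng, vaf, config.depth_mean)
            flags = frozenset({flag_pool[int(rng.integers(len(flag_pool)))]})
            tv = TruthVariant(
                key=key,
                gene=entry.gene,
                origin="artifact",
                in_panel=False,
                annotations=AnnotationBundle(gene=entry.gene, gene_role=entry.role),
            )
            if sample == "P":
                tv.evidence_P = (depth, alt, flags)
            else:
                tv.evidence_R = (depth, alt, flags)
            truth.variants.append(tv)

    # common germline polymorphisms: near-0.5 VAF in both samples, high pop AF
    for _ in range(config.n_polymorphisms):
        entry = config.driver_catalogue[int(rng.integers(len(config.driver_catalogue)))]
        key = _unique_key(rng, entry, used)
        bundle = AnnotationBundle(
            af_1kg=float(rng.uniform(0.05, 0.45)),
            af_gnomad_exome=float(rng.uniform(0.05, 0.45)),
            dbsnp_common=True,
            seq_ontology=SeqOntology.MISSENSE,
            effect=Effect.MISSENSE,
            clinical_class=ClinicalClass.BENIGN,
            gene=entry.gene,
            gene_role=entry.role,
        )
        tv = TruthVariant(
            key=key, gene=entry.gene, origin="polymorphism", in_panel=False,
            annotations=bundle,
        )
        for sample in ("P", "R"):
            vaf = float(np.clip(rng.normal(0.5, 0.05), 0.05, 0.95))
            depth, alt = _depth_alt_for_vaf(rng, vaf, config.depth_mean)
            if sample == "P":
                tv.evidence_P = (depth, alt, frozenset())
            else:
                tv.evidence_R = (depth, alt, frozenset())
        truth.variants.append(tv)

    # ---- write artifacts -------------------------------------------------
    paths = DuoPaths(
        vcf_p=out_dir / "primary.vcf",
        vcf_r=out_dir / "recurrent.vcf",
        annotations=out_dir / "annotations.tsv",
        panel=out_dir / "panel.txt",
        truth=out_dir / "truth.tsv",
    )
    _write_vcf(paths.vcf_p, f"{config.pair_id}-P", truth.variants, "P")
    _write_vcf(paths.vcf_r, f"{config.pair_id}-R", truth.variants, "R")
    write_annotations({tv.key: tv.annotations for tv in truth.variants}, paths.annotations)
    panel_genes = sorted(
        {e.gene for e in config.driver_catalogue} | set(_PANEL_PADDING)
    )
    paths.panel.write_text(
        "# synthetic glioma gene panel\n" + "\n".join(panel_genes) + "\n"
    )
    truth.to_frame().to_csv(paths.truth, sep="\t", index=False)
    return paths, truth


_CHROM_ORDER = {str(c): i for i, c in enumerate(list(range(1, 23)) + ["X", "Y"])}


def _write_vcf(path: Path, sample_id: str, variants: list[TruthVariant], sample: str) -> None:
    present = [
        (tv, tv.evidence_P if sample == "P" else tv.evidence_R)
        for tv in variants
        if (tv.evidence_P if sample == "P" else tv.evidence_R) is not None
    ]
    present.sort(key=lambda item: (_CHROM_ORDER.get(item[0].key[0], 99), item[0].key[1]))
    chroms = sorted(
        {tv.key[0] for tv, _ in present}, key=lambda c: _CHROM_ORDER.get(c, 99)
    )
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FILTER=<ID=strand_bias,Description="Evidence for strand bias">',
        '##FILTER=<ID=fragment,Description="Variant supported by improper fragments">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for tv, (depth, alt_depth, flags) in present:
        chrom, pos, ref, alt = tv.key
        filt = ";".join(sorted(flags)) if flags else "PASS"
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\t"
            f"GT:DP:AD\t0/1:{depth}:{depth - alt_depth},{alt_depth}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def _oracle_first_fail(
    tv: TruthVariant, sample: str, cfg: FilterConfig, panel_genes: set[str]
) -> str | None:
    """Straight-line re-derivation of the cascade fate from planted values.

    Intentionally independent of the filter_cascade module: plain if-chains
    over the truth's stored numbers, in the documented rule order.
    """
    ev = tv.evidence_P if sample == "P" else tv.evidence_R
    if ev is None:
        return "absent"
    depth, alt, flags = ev
    vaf = alt / depth if depth else 0.0
    b = tv.annotations
    # level 1
    if flags & cfg.excluded_caller_flags:
        return "caller_flag"
    if depth < cfg.min_depth:
        return "depth"
    if vaf < cfg.min_vaf:
        return "vaf"
    if alt < cfg.min_alt_reads:
        return "alt_reads"
    if b.af_1kg is not MISSING and b.af_1kg >= cfg.max_af_1kg:
        return "pop_af_1kg"
    if b.af_gnomad_exome is not MISSING and b.af_gnomad_exome >= cfg.max_af_gnomad:
        return "pop_af_gnomad"
    if b.maf_esp is not MISSING and b.maf_esp >= cfg.max_maf_esp:
        return "pop_maf_esp"
    if cfg.exclude_dbsnp_common and b.dbsnp_common:
        return "dbsnp_common"
    # level 2
    if b.seq_ontology.value in cfg.excluded_ontologies:
        return "ontology"
    damaging = sum(1 for v in b.predictor_verdicts.values() if v == Verdict.DAMAGING)
    if damaging < cfg.min_damaging_votes:
        return "prediction"
    if b.clinical_class is not MISSING and b.clinical_class.value in cfg.excluded_clinical_classes:
        return "clinical_class"
    if b.effect.value not in cfg.retained_effects:
        return "effect"
    if cfg.require_cosmic and not b.cosmic_ids:
        return "cosmic"
    # level 3
    if tv.gene.upper() not in panel_genes:
        return "panel"
    if b.gene_role.value not in cfg.retained_gene_roles:
        return "gene_role"
    return None


_LEVEL_OF = {
    "caller_flag": 1, "depth": 1, "vaf": 1, "alt_reads": 1,
    "pop_af_1kg": 1, "pop_af_gnomad": 1, "pop_maf_esp": 1, "dbsnp_common": 1,
    "ontology": 2, "prediction": 2, "clinical_class": 2, "effect": 2, "cosmic": 2,
    "panel": 3, "gene_role": 3,
}


def expected_counts(
    truth: SyntheticTruth,
    filter_config: FilterConfig | None = None,
    rescue_config: RescueConfig | None = None,
) -> dict:
    """Predict the pipeline's audit counts and duo tallies by enumeration."""
    fcfg = filter_config or FilterConfig()
    rcfg = rescue_config or RescueConfig()
    panel_genes = {e.gene for e in truth.config.driver_catalogue} | set(_PANEL_PADDING)
    out: dict = {"levels": {}, "duo": {}, "categories": {}}

    fates = {"P": {}, "R": {}}
    for sample in ("P", "R"):
        entering = 0
        survived = {1: 0, 2: 0, 3: 0}
        for tv in truth.variants:
            fate = _oracle_first_fail(tv, sample, fcfg, panel_genes)
            if fate == "absent":
                continue
            entering += 1
            fates[sample][tv.key] = fate
            failed_level = _LEVEL_OF[fate] if fate else 4
            for level in (1, 2, 3):
                if failed_level > level:
                    survived[level] += 1
        out["levels"][sample] = {
            "level1": {"entering": entering, "passing": survived[1]},
            "level2": {"entering": survived[1], "passing": survived[2]},
            "level3": {"entering": survived[2], "passing": survived[3]},
        }

    counts = {"P_ONLY": 0, "R_ONLY": 0, "SHARED": 0}
    cat_counts = {
        lab: {"SUM": 0, "O": 0, "LO": 0, "VUS": 0} for lab in ("GBM-P", "GBM-R", "GBM-S")
    }
    for tv in truth.variants:
        pass_p = fates["P"].get(tv.key, "absent") is None
        pass_r = fates["R"].get(tv.key, "absent") is None
        if not (pass_p or pass_r):
            continue
        if pass_p and pass_r:
            cat = "SHARED"
        else:
            partner_ev = tv.evidence_R if pass_p else tv.evidence_P
            rescued = False
            if partner_ev is not None and rcfg.search_raw:
                depth, alt, _ = partner_ev
                vaf = alt / depth if depth else 0.0
                rescued = alt >= rcfg.min_partner_alt_reads and vaf >= rcfg.min_partner_vaf
            cat = "SHARED" if rescued else ("P_ONLY" if pass_p else "R_ONLY")
        counts[cat] += 1
        label = {"P_ONLY": "GBM-P", "R_ONLY": "GBM-R", "SHARED": "GBM-S"}[cat]
        cat_counts[label]["SUM"] += 1
        cat_counts[label][tv.expected_class] += 1
    out["duo"] = counts
    out["categories"] = cat_counts
    return out
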