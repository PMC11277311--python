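"""Cohort-level summaries and the duo-pipeline orchestration behind the CLI.

Reports mirror the study's presentation: per-pair SUM/O/LO/VUS counts for the
primary-only, recurrent-only and shared categories with a Mean row; gene-by-
category and gene-by-ontology matrices over oncogenic and likely-oncogenic
variants; per-sample TMR rows; and per-pair heterogeneity trends.

Rounding convention for report rows: half-up to integers for Mean rows and to
2 decimals for TMR, with raw-precision companions always emitted. The Mean
row's SUM is the sum of the rounded component means (keeping SUM = O+LO+VUS
in the printed row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .duo_analysis import (
    DuoAssignment,
    DuoCategory,
    RescueConfig,
    categorize_duo,
    count_categories,
)
from .filter_cascade import FilterAudit, FilterConfig, apply_cascade, level1_quality_filter
from .oncogenicity import DEFAULT_RUBRIC, OncoClass, OncogenicityCall, Rubric, score_variant
from .tumor_metrics import SampleMetrics, Trend, heterogeneity_trend, round_half_up, sample_metrics
from .variant_model import (
    VariantKey,
    VariantRecord,
    attach_annotations,
    read_annotations,
    read_gene_panel,
    read_vcf,
)

__all__ = [
    "PairResult",
    "CohortSummary",
    "load_reference_table",
    "mean_row",
    "category_count_frame",
    "summarize_cohort",
    "recurrent_variant_table",
    "calls_frame",
    "process_duo",
]

_CATEGORY_PREFIX = {"GBM-P": "P", "GBM-R": "R", "GBM-S": "S"}
COUNT_COLUMNS = [
    f"{p}_{c}" for p in ("P", "R", "S") for c in ("SUM", "O", "LO", "VUS")
]


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one of the shipped published-cohort reference tables.

    Available names: ``category_counts``, ``tmr``, ``recurrent_variants``.
    """
    ref = resources.files("somaduo").joinpath(f"data/reference_cohort/{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"pair": str, "chrom": str})


@dataclass
class PairResult:
    """Everything the reports need about one fully processed duo."""

    pair_id: str
    raw_P: list[VariantRecord]
    raw_R: list[VariantRecord]
    passing_P: list[VariantRecord]
    passing_R: list[VariantRecord]
    audit_P: FilterAudit
    audit_R: FilterAudit
    assignment: DuoAssignment
    calls: dict[VariantKey, OncogenicityCall]
    records_by_key: dict[VariantKey, VariantRecord]
    metrics_P: SampleMetrics
    metrics_R: SampleMetrics

    @property
    def counts(self) -> dict[str, dict[str, int]]:
        return count_categories(self.assignment, self.calls)


@dataclass
class CohortSummary:
    """Aggregated cohort report (counts, matrices, TMR rows, trends)."""

    pair_rows: pd.DataFrame
    mean_raw: pd.Series
    mean_rounded: pd.Series
    gene_category: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_ontology: pd.DataFrame = field(default_factory=pd.DataFrame)
    tmr_rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    trends: dict[str, Trend] = field(default_factory=dict)


def mean_row(pair_rows: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Raw and printed Mean rows over per-pair count rows.

    Component means (O, LO, VUS per category) round half-up; each printed SUM
    is recomputed as the sum of its rounded components so the printed row
    still satisfies SUM = O + LO + VUS.
    """
    cols = [c for c in COUNT_COLUMNS if c in pair_rows.columns]
    raw = pair_rows[cols].mean()
    rounded = pd.Series(
        {c: int(round_half_up(raw[c], 0)) for c in cols}, dtype=int
    )
    for prefix in ("P", "R", "S"):
        if f"{prefix}_SUM" in rounded:
            rounded[f"{prefix}_SUM"] = (
                rounded[f"{prefix}_O"] + rounded[f"{prefix}_LO"] + rounded[f"{prefix}_VUS"]
            )
    return raw, rounded


def category_count_frame(
    counts_per_pair: Sequence[tuple[str, Mapping[str, Mapping[str, int]]]],
) -> pd.DataFrame:
    """Flatten count_categories outputs into one row per pair."""
    rows = []
    for pair_id, counts in counts_per_pair:
        row: dict = {"pair": pair_id}
        for label, prefix in _CATEGORY_PREFIX.items():
            for c in ("SUM", "O", "LO", "VUS"):
                row[f"{prefix}_{c}"] = counts[label][c]
        rows.append(row)
    return pd.DataFrame(rows, columns=["pair", *COUNT_COLUMNS])


def _olo_variant_rows(results: Sequence[PairResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for key, category in res.assignment.assignments.items():
            call = res.calls[key]
            if call.oclass is OncoClass.VUS:
                continue
            rec = res.records_by_key[key]
            rows.append(
                {
                    "pair": res.pair_id,
                    "gene": rec.annotations.gene,
                    "category": _CATEGORY_PREFIX[
                        {"P_ONLY": "GBM-P", "R_ONLY": "GBM-R", "SHARED": "GBM-S"}[category.value]
                    ],
                    "ontology": rec.annotations.seq_ontology.value,
                }
            )
    return pd.DataFrame(rows, columns=["pair", "gene", "category", "ontology"])


def summarize_cohort(results: Sequence[PairResult]) -> CohortSummary:
    """Aggregate fully processed pairs into the cohort report."""
    if not results:
        raise ValueError("summarize_cohort needs at least one processed pair")
    pair_rows = category_count_frame([(r.pair_id, r.counts) for r in results])
    raw, rounded = mean_row(pair_rows)

    olo = _olo_variant_rows(results)
    if olo.empty:
        gene_category = pd.DataFrame(columns=["P", "R", "S"])
        gene_ontology = pd.DataFrame()
    else:
        gene_category = (
            olo.pivot_table(index="gene", columns="category", aggfunc="size", fill_value=0)
            .reindex(columns=["P", "R", "S"], fill_value=0)
        )
        gene_ontology = olo.pivot_table(
            index="gene", columns="ontology", aggfunc="size", fill_value=0
        )

    tmr_rows = pd.DataFrame(
        [res.metrics_P.to_row() for res in results]
        + [res.metrics_R.to_row() for res in results]
    )
    trends = {
        res.pair_id: heterogeneity_trend(res.metrics_P.math_score, res.metrics_R.math_score)
        for res in results
        if res.metrics_P.math_score is not None and res.metrics_R.math_score is not None
    }
    return CohortSummary(
        pair_rows=pair_rows,
        mean_raw=raw,
        mean_rounded=rounded,
        gene_category=gene_category,
        gene_ontology=gene_ontology,
        tmr_rows=tmr_rows,
        trends=trends,
    )


def calls_frame(
    records: Iterable[VariantRecord],
    calls: Mapping[VariantKey, OncogenicityCall],
) -> pd.DataFrame:
    """Per-variant classification table consumed by recurrent_variant_table."""
    rows = []
    for r in records:
        call = calls[r.key]
        b = r.annotations
        rows.append(
            {
                "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
                "gene": b.gene, "hgvs_c": b.hgvs_c, "hgvs_p": b.hgvs_p,
                "seq_ontology": b.seq_ontology.value,
                "score": call.score, "oncogenicity": call.oclass.value,
                "cosmic_id": b.cosmic_ids[0] if b.cosmic_ids else "",
                "cosmic_count": b.cosmic_count,
            }
        )
    return pd.DataFrame(rows)


def recurrent_variant_table(
    calls: pd.DataFrame, min_catalogue_count: int = 15
) -> pd.DataFrame:
    """Oncogenic/likely-oncogenic variants recurrent in the cancer catalogue.

    Keeps rows classed O or LO with ``cosmic_count >= min_catalogue_count``,
    sorted by catalogue count descending.
    """
    if calls.empty:
        return calls.copy()
    kept = calls[
        calls["oncogenicity"].isin(["O", "LO"])
        & (calls["cosmic_count"] >= min_catalogue_count)
    ]
    return kept.sort_values(
        "cosmic_count", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def process_duo(
    vcf_p: str | Path,
    vcf_r: str | Path,
    annotations: str | Path,
    panel: str | Path,
    pair_id: str = "",
    filter_config: FilterConfig | None = None,
    rescue_config: RescueConfig | None = None,
    rubric: Rubric = DEFAULT_RUBRIC,
    capture_mb: float = 42.0,
    seed: int = 0,
) -> PairResult:
    """Run the full pipeline for one duo, from files to a PairResult.

    TMR, MATH and the VAF mixture are computed on each sample's level-1-
    passing variants; the cascade output feeds the duo categorization.
    """
    fcfg = filter_config or FilterConfig()
    rcfg = rescue_config or RescueConfig()
    bundles = read_annotations(annotations)
    panel_obj = read_gene_panel(panel)
    raw: dict[str, list[VariantRecord]] = {}
    passing: dict[str, list[VariantRecord]] = {}
    audits: dict[str, FilterAudit] = {}
    metrics: dict[str, SampleMetrics] = {}
    for tag, path in (("P", vcf_p), ("R", vcf_r)):
        sample_id = f"{pair_id}-{tag}" if pair_id else tag
        records = attach_annotations(read_vcf(path, sample_id), bundles)
        raw[tag] = records
        passing[tag], audits[tag] = apply_cascade(records, panel_obj, fcfg, sample_id)
        level1, _ = level1_quality_filter(records, fcfg)
        metrics[tag] = sample_metrics(
            sample_id, [r.vaf for r in level1], capture_mb=capture_mb, seed=seed
        )
    assignment = categorize_duo(
        passing["P"], passing["R"], raw["P"], raw["R"], rcfg, pair_id=pair_id
    )
    records_by_key: dict[VariantKey, VariantRecord] = {}
    for rec in (*passing["P"], *passing["R"]):
        records_by_key.setdefault(rec.key, rec)
    calls = {k: score_variant(rec, rubric) for k, rec in records_by_key.items()}
    return PairResult(
        pair_id=pair_id,
        raw_P=raw["P"],
        raw_R=raw["R"],
        passing_P=passing["P"],
        passing_R=passing["R"],
        audit_P=audits["P"],
        audit_R=audits["R"],
        assignment=assignment,
        calls=calls,
        records_by_key=records_by_key,
        metrics_P=metrics["P"],
        metrics_R=metrics["R"],
    )
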