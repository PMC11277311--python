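"""Three-level somatic variant filter cascade with a per-variant audit trail.

Level 1 removes technical artifacts and common polymorphisms: caller
hard-filter flags (strand bias, fragment), read depth, VAF and alt-read
thresholds, population allele frequencies, and dbSNP-common membership.
Level 2 keeps biologically relevant calls: non-silent ontology, at least one
damaging in-silico predictor vote, no benign-leaning clinical class, a
retained effect class, and catalogued cancer-mutation evidence.
Level 3 restricts to a disease gene panel with an annotated cancer-gene role.
A fourth, manual-curation stage is emitted as a ranked review table rather
than an algorithm.

Every removed variant carries exactly one first-fail reason, assigned in the
fixed rule order below, so audits are deterministic. Population-frequency
rules remove at >= threshold and never fire on MISSING values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
import yaml

from .variant_model import (
    MISSING,
    AnnotationBundle,
    ClinicalClass,
    Effect,
    GenePanel,
    GeneRole,
    SeqOntology,
    VariantKey,
    VariantRecord,
    Verdict,
)

__all__ = [
    "FilterConfig",
    "FilterAudit",
    "LevelAudit",
    "count_damaging_votes",
    "level1_quality_filter",
    "level2_relevance_filter",
    "level3_panel_filter",
    "apply_cascade",
    "review_report",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and rule sets for the cascade; defaults mirror the study design.

    Boundary semantics: quality thresholds retain at >= (DP >= 50, VAF >= 0.15,
    alt reads >= 20); population frequencies remove at >= their threshold.
    """

    min_depth: int = 50
    min_vaf: float = 0.15
    min_alt_reads: int = 20
    max_af_1kg: float = 0.02
    max_af_gnomad: float = 0.02
    max_maf_esp: float = 0.05
    exclude_dbsnp_common: bool = True
    excluded_ontologies: frozenset[str] = frozenset(
        {"initiator_codon", "intragenic", "intron", "synonymous"}
    )
    min_damaging_votes: int = 1
    excluded_clinical_classes: frozenset[str] = frozenset(
        {"benign", "likely_benign", "vus_weak_benign"}
    )
    retained_effects: frozenset[str] = frozenset({"LoF", "missense", "other", "unknown"})
    require_cosmic: bool = True
    retained_gene_roles: frozenset[str] = frozenset(
        {"oncogene", "tumor_suppressor", "fusion"}
    )
    excluded_caller_flags: frozenset[str] = frozenset({"strand_bias", "fragment"})

    def __post_init__(self) -> None:
        for name in ("min_vaf", "max_af_1kg", "max_af_gnomad", "max_maf_esp"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("min_depth", "min_alt_reads", "min_damaging_votes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        # normalize collections to frozensets so configs hash and round-trip
        for name in (
            "excluded_ontologies",
            "excluded_clinical_classes",
            "retained_effects",
            "retained_gene_roles",
            "excluded_caller_flags",
        ):
            object.__setattr__(self, name, frozenset(getattr(self, name)))

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for k, v in data.items():
            if isinstance(v, frozenset):
                data[k] = sorted(v)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
        return cls(**data)


# --- rule predicates -------------------------------------------------------
# Each rule returns True when the record FAILS it. Order fixes first-fail
# reason codes.


def count_damaging_votes(bundle: AnnotationBundle) -> int:
    """Number of in-silico predictors voting damaging; MISSING verdicts count 0."""
    return sum(
        1 for v in bundle.predictor_verdicts.values() if v == Verdict.DAMAGING
    )


def _af_removes(value: float | None, threshold: float) -> bool:
    return value is not MISSING and value >= threshold


_Rule = tuple[str, Callable[[VariantRecord, FilterConfig, GenePanel | None], bool]]

LEVEL1_RULES: Sequence[_Rule] = (
    ("caller_flag", lambda r, c, p: bool(r.caller_flags & c.excluded_caller_flags)),
    ("depth", lambda r, c, p: r.total_depth < c.min_depth),
    ("vaf", lambda r, c, p: r.vaf < c.min_vaf),
    ("alt_reads", lambda r, c, p: r.alt_depth < c.min_alt_reads),
    ("pop_af_1kg", lambda r, c, p: _af_removes(r.annotations.af_1kg, c.max_af_1kg)),
    (
        "pop_af_gnomad",
        lambda r, c, p: _af_removes(r.annotations.af_gnomad_exome, c.max_af_gnomad),
    ),
    ("pop_maf_esp", lambda r, c, p: _af_removes(r.annotations.maf_esp, c.max_maf_esp)),
    (
        "dbsnp_common",
        lambda r, c, p: c.exclude_dbsnp_common and r.annotations.dbsnp_common,
    ),
)

LEVEL2_RULES: Sequence[_Rule] = (
    (
        "ontology",
        lambda r, c, p: r.annotations.seq_ontology.value in c.excluded_ontologies,
    ),
    (
        "prediction",
        lambda r, c, p: count_damaging_votes(r.annotations) < c.min_damaging_votes,
    ),
    (
        "clinical_class",
        lambda r, c, p: r.annotations.clinical_class is not MISSING
        and r.annotations.clinical_class.value in c.excluded_clinical_classes,
    ),
    ("effect", lambda r, c, p: r.annotations.effect.value not in c.retained_effects),
    (
        "cosmic",
        lambda r, c, p: c.require_cosmic and not r.annotations.cosmic_ids,
    ),
)

LEVEL3_RULES: Sequence[_Rule] = (
    ("panel", lambda r, c, p: r.annotations.gene not in p),
    (
        "gene_role",
        lambda r, c, p: r.annotations.gene_role.value not in c.retained_gene_roles,
    ),
)


@dataclass
class LevelAudit:
    """Counts and first-fail reasons for one cascade level."""

    level: str
    entering: int
    passing: int
    removed: dict[VariantKey, str] = field(default_factory=dict)
    rules: tuple[str, ...] = ()


@dataclass
class FilterAudit:
    """Audit trail for a full cascade run on one sample."""

    sample_id: str
    levels: list[LevelAudit] = field(default_factory=list)

    @property
    def rules_applied(self) -> list[str]:
        return [rule for lv in self.levels for rule in lv.rules]

    def removal_reason(self, key: VariantKey) -> str | None:
        for lv in self.levels:
            if key in lv.removed:
                return lv.removed[key]
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"level": lv.level, "entering": lv.entering, "passing": lv.passing}
                for lv in self.levels
            ]
        )

    def removed_frame(self) -> pd.DataFrame:
        rows = [
            {
                "level": lv.level,
                "chrom": k[0],
                "pos": k[1],
                "ref": k[2],
                "alt": k[3],
                "reason": reason,
            }
            for lv in self.levels
            for k, reason in lv.removed.items()
        ]
        return pd.DataFrame(
            rows, columns=["level", "chrom", "pos", "ref", "alt", "reason"]
        )


def _apply_level(
    name: str,
    rules: Sequence[_Rule],
    records: Sequence[VariantRecord],
    config: FilterConfig,
    panel: GenePanel | None,
) -> tuple[list[VariantRecord], LevelAudit]:
    passing: list[VariantRecord] = []
    audit = LevelAudit(
        level=name,
        entering=len(records),
        passing=0,
        rules=tuple(rule_name for rule_name, _ in rules),
    )
    for r in records:
        reason = next(
            (rule_name for rule_name, fails in rules if fails(r, config, panel)), None
        )
        if reason is None:
            passing.append(r)
        else:
            audit.removed[r.key] = reason
    audit.passing = len(passing)
    return passing, audit


def level1_quality_filter(
    records: Sequence[VariantRecord], config: FilterConfig | None = None
) -> tuple[list[VariantRecord], LevelAudit]:
    """Technical-quality and common-polymorphism filter (cascade level 1)."""
    return _apply_level("level1", LEVEL1_RULES, records, config or FilterConfig(), None)


def level2_relevance_filter(
    records: Sequence[VariantRecord], config: FilterConfig | None = None
) -> tuple[list[VariantRecord], LevelAudit]:
    """Biological-relevance filter (cascade level 2)."""
    return _apply_level("level2", LEVEL2_RULES, records, config or FilterConfig(), None)


def level3_panel_filter(
    records: Sequence[VariantRecord],
    panel: GenePanel,
    config: FilterConfig | None = None,
) -> tuple[list[VariantRecord], LevelAudit]:
    """Gene-panel and cancer-gene-role filter (cascade level 3)."""
    return _apply_level("level3", LEVEL3_RULES, records, config or FilterConfig(), panel)


def apply_cascade(
    records: Sequence[VariantRecord],
    panel: GenePanel,
    config: FilterConfig | None = None,
    sample_id: str | None = None,
) -> tuple[list[VariantRecord], FilterAudit]:
    """Run levels 1 -> 2 -> 3 in order, collecting a full audit."""
    config = config or FilterConfig()
    if sample_id is None:
        sample_id = records[0].sample_id if records else ""
    audit = FilterAudit(sample_id=sample_id)
    out, lv1 = level1_quality_filter(records, config)
    audit.levels.append(lv1)
    out, lv2 = level2_relevance_filter(out, config)
    audit.levels.append(lv2)
    out, lv3 = level3_panel_filter(out, panel, config)
    audit.levels.append(lv3)
    return out, audit


def review_report(
    records: Iterable[VariantRecord],
    calls: dict[VariantKey, "OncogenicityCall"],  # noqa: F821 - see oncogenicity
) -> pd.DataFrame:
    """Manual-curation stage: rank cascade survivors for human review.

    One row per passing variant, sorted by oncogenicity score then catalogue
    sample count, both descending.
    """
    from .variant_model import variant_table

    records = list(records)
    df = variant_table(records)
    if df.empty:
        df["score"] = []
        df["oncogenicity"] = []
        return df
    df["score"] = [calls[r.key].score for r in records]
    df["oncogenicity"] = [calls[r.key].oclass.value for r in records]
    return df.sort_values(
        ["score", "cosmic_count"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
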