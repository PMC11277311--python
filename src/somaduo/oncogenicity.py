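"""Points-based oncogenicity scoring and threshold classing.

Each variant receives an additive integer score from a configurable rubric of
evidence rules (catalogue recurrence, loss-of-function in a tumor suppressor,
predictor consensus, splice disruption, population-frequency penalty), then a
class from two thresholds: Oncogenic at score >= 5, Likely oncogenic at 3-4,
VUS at <= 2. The thresholds are the published part of the scheme; the points
table is this package's replaceable rubric in the spirit of published
oncogenicity SOPs. Precomputed scores may be supplied instead of the rubric.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import yaml

from .filter_cascade import count_damaging_votes
from .variant_model import (
    MISSING,
    Effect,
    GeneRole,
    SeqOntology,
    VariantRecord,
)

__all__ = [
    "OncoClass",
    "OncogenicityCall",
    "RubricRule",
    "Rubric",
    "DEFAULT_RUBRIC",
    "classify",
    "score_variant",
]


class OncoClass(str, enum.Enum):
    ONCOGENIC = "O"
    LIKELY_ONCOGENIC = "LO"
    VUS = "VUS"


@dataclass(frozen=True)
class OncogenicityCall:
    score: int
    evidence_hits: tuple[str, ...]
    oclass: OncoClass


@dataclass(frozen=True)
class RubricRule:
    name: str
    predicate: Callable[[VariantRecord], bool]
    points: int


def _catalogue_high(r: VariantRecord) -> bool:
    return r.annotations.cosmic_count >= 50


def _catalogue_mid(r: VariantRecord) -> bool:
    return 10 <= r.annotations.cosmic_count < 50


def _catalogue_low(r: VariantRecord) -> bool:
    return 1 <= r.annotations.cosmic_count < 10


def _lof_in_tsg(r: VariantRecord) -> bool:
    return (
        r.annotations.effect == Effect.LOF
        and r.annotations.gene_role == GeneRole.TUMOR_SUPPRESSOR
    )


def _missense_consensus(r: VariantRecord) -> bool:
    return (
        r.annotations.seq_ontology == SeqOntology.MISSENSE
        and count_damaging_votes(r.annotations) >= 3
    )


def _splice(r: VariantRecord) -> bool:
    return r.annotations.seq_ontology == SeqOntology.SPLICE_VARIANT


def _oncogene_recurrent(r: VariantRecord) -> bool:
    return r.annotations.gene_role == GeneRole.ONCOGENE and r.annotations.cosmic_count >= 10


def _population_seen(r: VariantRecord) -> bool:
    b = r.annotations
    return any(
        v is not MISSING and v > 0 for v in (b.af_1kg, b.af_gnomad_exome, b.maf_esp)
    )


@dataclass(frozen=True)
class Rubric:
    """Ordered evidence rules with points, plus the two class thresholds.

    Catalogue-recurrence tiers are mutually exclusive (a variant scores the
    single tier its sample count falls in). Points may be negative.
    """

    rules: tuple[RubricRule, ...]
    oncogenic_min: int = 5
    likely_min: int = 3

    def __post_init__(self) -> None:
        if not (self.oncogenic_min > self.likely_min >= 1):
            raise ValueError(
                f"thresholds must satisfy oncogenic_min > likely_min >= 1, "
                f"got {self.oncogenic_min}, {self.likely_min}"
            )

    def to_yaml(self, path: str | Path) -> None:
        """Serialize names/points/thresholds (predicates are the shipped set)."""
        data = {
            "oncogenic_min": self.oncogenic_min,
            "likely_min": self.likely_min,
            "points": {rule.name: rule.points for rule in self.rules},
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Rubric":
        data = yaml.safe_load(Path(path).read_text())
        points = data.get("points", {})
        unknown = set(points) - set(_DEFAULT_PREDICATES)
        if unknown:
            raise ValueError(f"unknown rubric rule names: {sorted(unknown)}")
        rules = tuple(
            RubricRule(name, _DEFAULT_PREDICATES[name], int(pts))
            for name, pts in points.items()
        )
        return cls(
            rules=rules,
            oncogenic_min=int(data.get("oncogenic_min", 5)),
            likely_min=int(data.get("likely_min", 3)),
        )


_DEFAULT_PREDICATES: dict[str, Callable[[VariantRecord], bool]] = {
    "catalogue_recurrence_high": _catalogue_high,
    "catalogue_recurrence_mid": _catalogue_mid,
    "catalogue_recurrence_low": _catalogue_low,
    "lof_in_tumor_suppressor": _lof_in_tsg,
    "missense_predictor_consensus": _missense_consensus,
    "splice_disruption": _splice,
    "oncogene_recurrent": _oncogene_recurrent,
    "population_frequency_seen": _population_seen,
}

_DEFAULT_POINTS = {
    "catalogue_recurrence_high": 4,
    "catalogue_recurrence_mid": 2,
    "catalogue_recurrence_low": 1,
    "lof_in_tumor_suppressor": 4,
    "missense_predictor_consensus": 2,
    "splice_disruption": 2,
    "oncogene_recurrent": 2,
    "population_frequency_seen": -4,
}

DEFAULT_RUBRIC = Rubric(
    rules=tuple(
        RubricRule(name, _DEFAULT_PREDICATES[name], _DEFAULT_POINTS[name])
        for name in _DEFAULT_POINTS
    )
)


def classify(
    score: int, oncogenic_min: int = 5, likely_min: int = 3
) -> OncoClass:
    """Map an integer score to a class; total over all integers (negatives -> VUS)."""
    if score >= oncogenic_min:
        return OncoClass.ONCOGENIC
    if score >= likely_min:
        return OncoClass.LIKELY_ONCOGENIC
    return OncoClass.VUS


def score_variant(
    record: VariantRecord, rubric: Rubric = DEFAULT_RUBRIC
) -> OncogenicityCall:
    """Score one annotated record: sum fired rule points, then class by threshold."""
    hits = tuple(rule.name for rule in rubric.rules if rule.predicate(record))
    score = sum(rule.points for rule in rubric.rules if rule.name in hits)
    return OncogenicityCall(
        score=score,
        evidence_hits=hits,
        oclass=classify(score, rubric.oncogenic_min, rubric.likely_min),
    )
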