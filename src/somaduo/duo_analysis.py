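"""Paired-sample (duo) categorization of cascade-passing variants.

A matched primary/recurrent pair is analyzed jointly: variants passing the
filter cascade in both samples are Shared; a variant passing in only one
sample triggers a rescue search in the partner's raw (pre-filter) calls, and
is promoted to Shared when allele-exact supporting evidence clears the rescue
thresholds. Otherwise it stays Primary-only or Recurrent-only. Shared
variants are counted once per pair.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .oncogenicity import OncoClass, OncogenicityCall
from .variant_model import VariantKey, VariantRecord

__all__ = [
    "DuoCategory",
    "RescueConfig",
    "RescueEvidence",
    "DuoAssignment",
    "rescue_lookup",
    "categorize_duo",
    "count_categories",
]


class DuoCategory(str, enum.Enum):
    P_ONLY = "P_ONLY"
    R_ONLY = "R_ONLY"
    SHARED = "SHARED"


@dataclass(frozen=True)
class RescueConfig:
    """Evidence floor for promoting a one-sided variant to Shared.

    ``search_raw`` searches the partner's pre-filter calls (the default);
    switching it off restricts the search to the partner's passing set, which
    makes rescue a no-op.
    """

    min_partner_alt_reads: int = 5
    min_partner_vaf: float = 0.05
    search_raw: bool = True

    def __post_init__(self) -> None:
        if self.min_partner_alt_reads < 0 or self.min_partner_vaf < 0:
            raise ValueError("rescue thresholds must be non-negative")


@dataclass(frozen=True)
class RescueEvidence:
    key: VariantKey
    rescued_in: str
    partner_alt_depth: int
    partner_vaf: float


@dataclass
class DuoAssignment:
    """Disjoint, exhaustive partition of a pair's passing variants."""

    pair_id: str
    assignments: dict[VariantKey, DuoCategory] = field(default_factory=dict)
    rescue_events: list[RescueEvidence] = field(default_factory=list)

    def keys_in(self, category: DuoCategory) -> set[VariantKey]:
        return {k for k, c in self.assignments.items() if c is category}

    def to_frame(self) -> pd.DataFrame:
        rescued = {e.key: e for e in self.rescue_events}
        rows = []
        for key in sorted(self.assignments):
            ev = rescued.get(key)
            rows.append(
                {
                    "pair_id": self.pair_id,
                    "chrom": key[0],
                    "pos": key[1],
                    "ref": key[2],
                    "alt": key[3],
                    "category": self.assignments[key].value,
                    "rescued_in": ev.rescued_in if ev else "",
                    "partner_alt_depth": ev.partner_alt_depth if ev else "",
                    "partner_vaf": ev.partner_vaf if ev else "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "pair_id", "chrom", "pos", "ref", "alt", "category",
                "rescued_in", "partner_alt_depth", "partner_vaf",
            ],
        )


def rescue_lookup(
    variant_key: VariantKey,
    partner_raw_records: Iterable[VariantRecord],
    rescue_config: RescueConfig | None = None,
) -> tuple[bool, RescueEvidence | None]:
    """Search the partner's calls for allele-exact support above the rescue floor."""
    cfg = rescue_config or RescueConfig()
    for r in partner_raw_records:
        if (
            r.key == variant_key
            and r.alt_depth >= cfg.min_partner_alt_reads
            and r.vaf >= cfg.min_partner_vaf
        ):
            return True, RescueEvidence(
                key=variant_key,
                rescued_in=r.sample_id,
                partner_alt_depth=r.alt_depth,
                partner_vaf=r.vaf,
            )
    return False, None


def categorize_duo(
    passing_P: Sequence[VariantRecord],
    passing_R: Sequence[VariantRecord],
    raw_P: Sequence[VariantRecord],
    raw_R: Sequence[VariantRecord],
    rescue_config: RescueConfig | None = None,
    pair_id: str = "",
) -> DuoAssignment:
    """Partition the union of both passing sets into P-only / R-only / Shared."""
    cfg = rescue_config or RescueConfig()
    keys_P = {r.key for r in passing_P}
    keys_R = {r.key for r in passing_R}
    # index raw partner calls once; rescue searches pre-filter calls by default
    search_R = raw_R if cfg.search_raw else passing_R
    search_P = raw_P if cfg.search_raw else passing_P

    out = DuoAssignment(pair_id=pair_id)
    for key in keys_P | keys_R:
        if key in keys_P and key in keys_R:
            out.assignments[key] = DuoCategory.SHARED
        elif key in keys_P:
            rescued, ev = rescue_lookup(key, search_R, cfg)
            if rescued:
                out.assignments[key] = DuoCategory.SHARED
                out.rescue_events.append(ev)
            else:
                out.assignments[key] = DuoCategory.P_ONLY
        else:
            rescued, ev = rescue_lookup(key, search_P, cfg)
            if rescued:
                out.assignments[key] = DuoCategory.SHARED
                out.rescue_events.append(ev)
            else:
                out.assignments[key] = DuoCategory.R_ONLY
    return out


_CATEGORY_LABELS = {
    DuoCategory.P_ONLY: "GBM-P",
    DuoCategory.R_ONLY: "GBM-R",
    DuoCategory.SHARED: "GBM-S",
}


def count_categories(
    assignment: DuoAssignment,
    classified_calls: Mapping[VariantKey, OncogenicityCall | OncoClass],
) -> dict[str, dict[str, int]]:
    """Tally SUM/O/LO/VUS per duo category; shared variants count once.

    ``classified_calls`` maps every assigned variant key to its oncogenicity
    call (or bare class); an unclassified variant is an error.
    """
    counts = {
        label: {"SUM": 0, "O": 0, "LO": 0, "VUS": 0}
        for label in _CATEGORY_LABELS.values()
    }
    for key, category in assignment.assignments.items():
        if key not in classified_calls:
            raise KeyError(f"variant {key} has no oncogenicity call")
        call = classified_calls[key]
        oclass = call.oclass if isinstance(call, OncogenicityCall) else OncoClass(call)
        label = _CATEGORY_LABELS[category]
        counts[label]["SUM"] += 1
        counts[label][oclass.value] += 1
    return counts
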