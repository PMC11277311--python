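"""Filter-cascade rules, audit bookkeeping, and cascade-level properties."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from somaduo.filter_cascade import (
    FilterConfig,
    apply_cascade,
    count_damaging_votes,
    level1_quality_filter,
    level2_relevance_filter,
    level3_panel_filter,
)
from somaduo.variant_model import (
    ClinicalClass,
    Effect,
    GenePanel,
    GeneRole,
    SeqOntology,
)

from conftest import make_bundle, make_record

PANEL = GenePanel(frozenset({"TP53", "PTEN", "EGFR"}))


def reasons(audit_fragment):
    return set(audit_fragment.removed.values())


class TestLevel1:
    def test_inclusive_boundaries_retain(self):
        rec = make_record(depth=50, alt=20)  # vaf 0.40
        rec2 = make_record(depth=133, alt=20)  # vaf 0.1504 >= 0.15
        passing, frag = level1_quality_filter([rec, rec2])
        assert len(passing) == 2 and not frag.removed

    def test_exact_vaf_boundary(self):
        rec = make_record(depth=200, alt=30)  # vaf exactly 0.15
        passing, _ = level1_quality_filter([rec])
        assert passing

    @pytest.mark.parametrize(
        "kwargs, reason",
        [
            (dict(depth=49, alt=20), "depth"),
            (dict(depth=300, alt=30), "vaf"),  # vaf 0.10 < 0.15
            (dict(depth=60, alt=19), "alt_reads"),
            (dict(flags=frozenset({"strand_bias"})), "caller_flag"),
            (dict(flags=frozenset({"fragment"})), "caller_flag"),
            (dict(af_1kg=0.02), "pop_af_1kg"),
            (dict(af_gnomad_exome=0.02), "pop_af_gnomad"),
            (dict(maf_esp=0.05), "pop_maf_esp"),
            (dict(dbsnp_common=True), "dbsnp_common"),
        ],
    )
    def test_first_fail_reasons(self, kwargs, reason):
        flags = kwargs.pop("flags", frozenset())
        rec = make_record(
            depth=kwargs.pop("depth", 100),
            alt=kwargs.pop("alt", 40),
            flags=flags,
            bundle=make_bundle(**kwargs),
        )
        passing, frag = level1_quality_filter([rec])
        assert not passing
        assert frag.removed[rec.key] == reason

    def test_missing_population_frequencies_are_retained(self):
        rec = make_record(bundle=make_bundle(af_1kg=None, af_gnomad_exome=None, maf_esp=None))
        passing, _ = level1_quality_filter([rec])
        assert passing

    def test_frequency_below_threshold_retained(self):
        rec = make_record(bundle=make_bundle(af_1kg=0.0199, af_gnomad_exome=0.0, maf_esp=0.049))
        passing, _ = level1_quality_filter([rec])
        assert passing


class TestDamagingVotes:
    @pytest.mark.parametrize("n_damaging, expected", [(6, 6), (0, 0), (1, 1)])
    def test_vote_counting(self, n_damaging, expected):
        assert count_damaging_votes(make_bundle(damaging=n_damaging)) == expected

    def test_all_missing_verdicts_count_zero(self):
        b = make_bundle()
        object.__setattr__(b, "predictor_verdicts", {p: None for p in b.predictor_verdicts})
        assert count_damaging_votes(b) == 0


class TestLevel2:
    @pytest.mark.parametrize(
        "kwargs, reason",
        [
            (dict(ontology=SeqOntology.SYNONYMOUS), "ontology"),
            (dict(ontology=SeqOntology.INTRON), "ontology"),
            (dict(damaging=0), "prediction"),
            (dict(clinical=ClinicalClass.BENIGN), "clinical_class"),
            (dict(clinical=ClinicalClass.VUS_WEAK_BENIGN), "clinical_class"),
            (dict(effect=Effect.NONE), "effect"),
            (dict(cosmic_ids=()), "cosmic"),
        ],
    )
    def test_first_fail_reasons(self, kwargs, reason):
        rec = make_record(bundle=make_bundle(**kwargs))
        passing, frag = level2_relevance_filter([rec])
        assert not passing and frag.removed[rec.key] == reason

    def test_qualifying_missense_passes(self):
        rec = make_record(
            bundle=make_bundle(damaging=1, clinical=ClinicalClass.OTHER, cosmic_ids=("COSM9",))
        )
        passing, _ = level2_relevance_filter([rec])
        assert passing

    def test_missing_clinical_class_is_retained(self):
        rec = make_record(bundle=make_bundle(clinical=None))
        passing, _ = level2_relevance_filter([rec])
        assert passing


class TestLevel3:
    def test_panel_tumor_suppressor_passes(self):
        rec = make_record(bundle=make_bundle(gene="TP53", role=GeneRole.TUMOR_SUPPRESSOR))
        passing, _ = level3_panel_filter([rec], PANEL)
        assert passing

    def test_in_panel_gene_without_role_removed(self):
        rec = make_record(bundle=make_bundle(gene="PTEN", role=GeneRole.NONE))
        passing, frag = level3_panel_filter([rec], PANEL)
        assert not passing and frag.removed[rec.key] == "gene_role"

    def test_off_panel_oncogene_removed(self):
        rec = make_record(bundle=make_bundle(gene="KRAS", role=GeneRole.ONCOGENE))
        passing, frag = level3_panel_filter([rec], PANEL)
        assert not passing and frag.removed[rec.key] == "panel"

    def test_panel_match_is_case_insensitive(self):
        rec = make_record(bundle=make_bundle(gene="tp53"))
        passing, _ = level3_panel_filter([rec], PANEL)
        assert passing


def _mixed_records(n=40, seed=0):
    rng = random.Random(seed)
    records = []
    for i in range(n):
        depth = rng.choice([30, 49, 50, 120, 250])
        records.append(
            make_record(
                depth=depth,
                alt=min(rng.choice([5, 19, 20, 45]), depth),
                flags=frozenset({"strand_bias"}) if rng.random() < 0.25 else frozenset(),
                pos=1000 + i,
                bundle=make_bundle(
                    damaging=rng.randint(0, 6),
                    ontology=rng.choice(list(SeqOntology)),
                    gene=rng.choice(["TP53", "PTEN", "EGFR", "KRAS"]),
                    role=rng.choice(list(GeneRole)),
                    cosmic_ids=("COSM1",) if rng.random() < 0.7 else (),
                    af_1kg=rng.choice([None, 0.001, 0.05]),
                ),
            )
        )
    return records


class TestCascade:
    def test_empty_input_gives_empty_audit(self):
        passing, audit = apply_cascade([], PANEL)
        assert passing == []
        assert [(lv.entering, lv.passing) for lv in audit.levels] == [(0, 0)] * 3

    def test_idempotence_and_monotonicity(self):
        records = _mixed_records()
        once, audit = apply_cascade(records, PANEL)
        twice, audit2 = apply_cascade(once, PANEL)
        assert [r.key for r in twice] == [r.key for r in once]
        keys = {r.key for r in records}
        for lv in audit.levels:
            assert lv.passing <= lv.entering
            assert set(lv.removed) <= keys

    def test_audit_conservation_and_chaining(self):
        records = _mixed_records(seed=3)
        _, audit = apply_cascade(records, PANEL)
        for prev, nxt in zip(audit.levels, audit.levels[1:]):
            assert prev.passing == nxt.entering
        for lv in audit.levels:
            assert lv.entering - lv.passing == len(lv.removed)

    def test_each_removed_variant_has_one_reason(self):
        records = _mixed_records(seed=4)
        passing, audit = apply_cascade(records, PANEL)
        removed_keys = [k for lv in audit.levels for k in lv.removed]
        assert len(removed_keys) == len(set(removed_keys))
        assert len(passing) + len(removed_keys) == len(records)

    def test_order_independence_within_levels(self):
        records = _mixed_records(seed=5)
        shuffled = records[::-1]
        a, _ = apply_cascade(records, PANEL)
        b, _ = apply_cascade(shuffled, PANEL)
        assert {r.key for r in a} == {r.key for r in b}

    def test_config_yaml_round_trip_gives_identical_results(self, tmp_path):
        cfg = FilterConfig(min_depth=60, excluded_caller_flags=frozenset({"strand_bias"}))
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        cfg2 = FilterConfig.from_yaml(path)
        assert cfg2 == cfg
        records = _mixed_records(seed=6)
        a, _ = apply_cascade(records, PANEL, cfg)
        b, _ = apply_cascade(records, PANEL, cfg2)
        assert [r.key for r in a] == [r.key for r in b]

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("min_depht: 60\n")
        with pytest.raises(ValueError, match="min_depht"):
            FilterConfig.from_yaml(path)


@settings(max_examples=50, deadline=None)
@given(
    depth=st.integers(min_value=1, max_value=400),
    alt_frac=st.floats(min_value=0, max_value=1),
    damaging=st.integers(min_value=0, max_value=6),
    flagged=st.booleans(),
)
def test_cascade_is_idempotent_property(depth, alt_frac, damaging, flagged):
    rec = make_record(
        depth=depth,
        alt=int(alt_frac * depth),
        flags=frozenset({"fragment"}) if flagged else frozenset(),
        bundle=make_bundle(damaging=damaging),
    )
    once, _ = apply_cascade([rec], PANEL)
    twice, _ = apply_cascade(once, PANEL)
    assert [r.key for r in once] == [r.key for r in twice]
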