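from __future__ import annotations

import pytest

from somaduo.variant_model import (
    MISSING,
    AnnotationBundle,
    ClinicalClass,
    Effect,
    GeneRole,
    PREDICTORS,
    SeqOntology,
    VariantRecord,
    Verdict,
)


def make_bundle(
    damaging: int = 3,
    ontology: SeqOntology = SeqOntology.MISSENSE,
    effect: Effect = Effect.MISSENSE,
    gene: str = "TP53",
    role: GeneRole = GeneRole.TUMOR_SUPPRESSOR,
    cosmic_count: int = 30,
    cosmic_ids: tuple[str, ...] = ("COSM1",),
    clinical: ClinicalClass | None = MISSING,
    **kwargs,
) -> AnnotationBundle:
    verdicts = {
        p: (Verdict.DAMAGING if i < damaging else Verdict.TOLERATED)
        for i, p in enumerate(PREDICTORS)
    }
    return AnnotationBundle(
        seq_ontology=ontology,
        effect=effect,
        predictor_verdicts=verdicts,
        clinical_class=clinical,
        cosmic_ids=cosmic_ids,
        cosmic_count=cosmic_count,
        gene=gene,
        gene_role=role,
        **kwargs,
    )


def make_record(
    depth: int = 100,
    alt: int = 40,
    flags: frozenset[str] = frozenset(),
    pos: int = 1000,
    chrom: str = "17",
    sample_id: str = "S",
    bundle: AnnotationBundle | None = None,
    **bundle_kwargs,
) -> VariantRecord:
    return VariantRecord(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref="C",
        alt="T",
        total_depth=depth,
        alt_depth=alt,
        caller_flags=flags,
        annotations=bundle if bundle is not None else make_bundle(**bundle_kwargs),
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def bundle_factory():
    return make_bundle


@pytest.fixture(scope="session")
def default_duo(tmp_path_factory):
    """One simulated duo under default study-shaped conditions."""
    from somaduo.synthetic_cohort import SimConfig, simulate_duo

    out = tmp_path_factory.mktemp("duo")
    paths, truth = simulate_duo(SimConfig(seed=11), out)
    return paths, truth


@pytest.fixture(scope="session")
def default_duo_result(default_duo):
    from somaduo.reporting import process_duo

    paths, truth = default_duo
    res = process_duo(
        paths.vcf_p, paths.vcf_r, paths.annotations, paths.panel,
        pair_id="pair1", seed=11,
    )
    return res, truth
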