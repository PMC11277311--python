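# Methods

## Scope and model of the data

The package operates on per-sample somatic variant calls from matched
primary/recurrent tumor pairs. A call is a single (chrom, pos, ref, alt)
allele in one sample with a read depth, an alt-supporting read count, and a
set of caller hard-filter flags; multiallelic VCF sites are split into one
record per ALT allele on read. VAF is always recomputed as alt/depth so that
the jointly stated depth, alt-count and VAF thresholds act on mutually
consistent numbers; a caller-provided AF field is ignored. Indel
normalisation and left-alignment are assumed done upstream and are not
enforced. Annotation joins are allele-exact on (chrom, pos, ref, alt);
gene symbols are compared case-insensitively after trimming, because panels
and annotation sources disagree on casing.

MISSING is a first-class annotation value, distinct from zero: a variant
absent from a population resource is not treated as rare-with-frequency-0,
and population-frequency removals never fire on MISSING.

## Filter cascade

Three per-record conjunctive levels, applied in order; each level's passing
set is a subset of its input, so the cascade is idempotent and
order-independent within levels. Defaults:

| rule | default | semantics |
|---|---|---|
| caller flags | {strand_bias, fragment} | any overlap removes |
| depth | ≥ 50 | inclusive retention |
| VAF | ≥ 0.15 | inclusive retention |
| alt reads | ≥ 20 | inclusive retention |
| 1kG / gnomAD AF | < 0.02 | removal at ≥ threshold; MISSING retained |
| ESP MAF | < 0.05 | same |
| dbSNP common | excluded | boolean |
| ontology | drop initiator_codon, intragenic, intron, synonymous | |
| predictor votes | ≥ 1 damaging of 6 | MISSING verdicts count 0 |
| clinical class | drop benign, likely_benign, vus_weak_benign | MISSING retained |
| effect | keep LoF, missense, other, unknown | |
| catalogue | ≥ 1 COSMIC ID required | |
| panel | gene ∈ panel | |
| gene role | oncogene, tumor_suppressor, fusion | |

The predictor rule is stated ambiguously in the pipeline this design
follows; we retain records with at least `min_damaging_votes` damaging
votes (a pathogenicity *enrichment*), exposing the threshold in config.
Each removed record gets exactly one first-fail reason, assigned in the
fixed order above — the order matters only for reason attribution, never
for the passing set (conjunction). The fourth, manual-curation stage is a
ranked review TSV (score desc, then catalogue count desc), not an
algorithm. The proprietary "technically hard to detect" flag system of the
original tooling is represented only by the configurable excluded-flag set.

## Duo categorization and rescue

The unit of analysis is the union of both samples' cascade-passing variant
keys, partitioned into P-only / R-only / Shared; shared variants count once
per pair. A one-sided variant is rescued to Shared when the partner's raw
(pre-filter) calls contain the same allele with alt reads ≥ 5 and VAF ≥ 5%.
These two floors are this package's choice (the original tooling's rescue
internals are not published): they demand multi-read support while
tolerating FFPE degradation of the partner sample; both are configurable,
and `search_raw=False` restricts the search to the partner's passing set
(making rescue a no-op). Lowering the floors can only grow the Shared set
(rescue monotonicity); swapping the samples swaps the two private
categories and fixes Shared.

## Oncogenicity scoring

Class thresholds are the published part: score ≥ 5 → Oncogenic, 3–4 →
Likely oncogenic, ≤ 2 (including negatives) → VUS. The additive points
rubric behind the score is this package's replaceable stand-in for a
proprietary classifier, in the spirit of published oncogenicity SOPs:

* catalogue recurrence (exclusive tiers): count ≥ 50 → +4, 10–49 → +2,
  1–9 → +1;
* LoF in a tumor suppressor → +4;
* missense with ≥ 3 damaging predictor votes → +2;
* splice variant → +2;
* oncogene with catalogue count ≥ 10 → +2;
* any non-zero population frequency → −4.

Additivity is a modeling choice; scores may also be supplied precomputed in
the annotation table and fed straight to `classify`. The rubric's names,
points and thresholds round-trip through YAML.

## Tumor metrics

**TMR** = level-1-passing count / capture size (default 42 Mb), with
log10(per-Mb) undefined at zero mutations. Level-1 output is the input by
design; no separate 20× depth rule is applied, since the level-1 thresholds
(DP ≥ 50, alt ≥ 20) already dominate it. TMR is a longitudinal change
indicator and deliberately not comparable to clinical TMB.

**MATH** = 100 · MAD / median of the sample's VAFs. The MAD uses the
normal-consistency constant 1.4826 by default (the convention of the
original score definition and of R's `mad`); `mad_scale=1.0` gives the
unscaled variant. MATH is scale-invariant under VAF rescaling and zero for
constant VAFs; a zero median yields an undefined score with a warning.

**VAF mixture.** A 1-D Gaussian mixture is fitted by EM for k = 1..5 in two
families — equal variance ("E") and free variance ("V") — and the model
minimising BIC = −2·logL + p·ln n is selected (ties to smaller k, then E).
EM details: component means initialised at the data quantiles
(i + 0.5)/k, uniform weights, pooled-variance start; convergence at
|ΔlogL| < 1e-8, max 500 iterations; variance floor 1e-8 against
degenerate spikes. The quantile initialisation makes fits deterministic and
input-order invariant; the seed is kept only for optional perturbed
restarts (off by default). Per-iteration log-likelihood monotonicity is
asserted inside the fit — a decrease raises immediately. The EM is written
in-package so the ascent property is checkable; scikit-learn's
GaussianMixture serves as an independent cross-check in the test suite,
not as the implementation.

**Trend** is the sign of MATH(recurrent) − MATH(primary).

## Synthetic cohorts and the enumeration oracle

The generator's defaults describe one plausible deep-FFPE-exome duo:
depth ~ Poisson(180) (deep exome coverage of FFPE tissue), clone VAF
centers (0.45, 0.26) in the primary and (0.48, 0.30) in the recurrent
sample with sd 0.03, 8 trunk + 6/9 private true variants, 40/50 flagged
C>T artifacts per sample at VAF 0.01–0.10 (formalin-deamination surrogate),
15 shared polymorphisms near VAF 0.5 with population AF 0.05–0.45 and
dbSNP-common set, 80% of true variants on panel genes, and one trunk
variant degraded in the recurrent sample below the VAF floor but above the
rescue floor. Alt counts are rounded from drawn VAFs, so the emitted VAF is
exactly alt/depth. Outputs (two VCFs, annotation TSV, panel, truth TSV) are
byte-identical for a given config.

Planted annotations come from a fixed driver catalogue (TP53, PTEN, EGFR,
KMT2D, APC, RB1, CREBBP, SMARCA4, ...) whose roles, ontologies and
catalogue counts span all three oncogenicity classes; each entry carries a
hand-summed expected score/class used as a classifier oracle.

`expected_counts` re-derives every per-level audit count, duo tally and
class tally by straight-line enumeration over the truth table — an
intentionally separate code path from the pipeline, so agreement between
the two is a genuine end-to-end check.

What the generator does *not* emulate: sequencing-error VAF noise beyond
clone scatter, positional artifact clustering, copy-number distortion of
VAFs, tumor purity, indel realignment ambiguity, or realistic per-gene
mutation rates. Passing the truth-recovery tests therefore demonstrates the
pipeline's bookkeeping and rule logic, not calling accuracy on real tumors.

## Reporting conventions

Mean rows over per-pair category counts round half-up to integers, and the
printed SUM of a mean row is the sum of the rounded O/LO/VUS means — this
keeps SUM = O + LO + VUS inside the printed row (the convention the
reference cohort table itself follows); raw means are always emitted
alongside. TMR report values round half-up to 2 decimals with raw
companions. The recurrent-variant table keeps O/LO variants at catalogue
count ≥ 15 by default, sorted descending. Gene-by-category and
gene-by-ontology matrices tally O/LO variants only, so their grand totals
match the O+LO category counts.

## Problem sizes used in validation

Truth-recovery checks run 20 simulated duos (~70 variants per sample);
mixture recovery uses 100 replicates of n = 300 (two components at
0.20/0.50, sd 0.02, and one at 0.40). These sizes give stable pass/fail
behaviour for the stochastic checks while keeping the suite quick to run.

## Known limitations

* The filter cascade consumes caller flags as given; it does not
  re-implement the upstream caller's internal logic.
* The oncogenicity rubric is a stand-in calibrated only at the
  threshold/class level; absolute scores are not comparable to any
  proprietary classifier's.
* No clone-tree reconstruction, CNV handling, germline ACMG classification
  or therapeutic tiering.
* The shipped 60-odd-gene demonstration panel is for testing and examples;
  real analyses should supply their own panel file.
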