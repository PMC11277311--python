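# somaduo

Somatic variant triage for matched primary/recurrent tumor pairs ("duos"),
built around the analysis style used for longitudinal glioblastoma (GBM)
exome studies on FFPE tissue. It is aimed at bioinformaticians who receive
per-sample somatic VCFs (Mutect2-style, with `DP`/`AD` FORMAT fields and
caller hard-filter FILTER labels) plus tabular annotations, and need a
reproducible, fully audited path from raw calls to a reviewable set of
oncogenic drivers and longitudinal tumor metrics.

## What it computes

**Filter cascade (levels 1–3, audited).** Level 1 removes technical and
population noise: strand-bias/fragment-flagged calls, depth < 50, VAF < 15%,
alt reads < 20, population allele frequency ≥ 2% (1000 Genomes, gnomAD
exomes) or ≥ 5% (ESP), and dbSNP-common variants (MISSING frequencies are
retained). Level 2 keeps relevant calls: non-silent sequence ontology, ≥ 1
damaging vote among six in-silico predictors (SIFT, PolyPhen2-HVAR,
MutationTaster, MutationAssessor, FATHMM, FATHMM-MKL), no benign-leaning
clinical class, a retained effect class, and ≥ 1 cancer-catalogue (COSMIC)
record. Level 3 restricts to a glioma gene panel with an annotated
oncogene/tumor-suppressor/fusion role. Every removed variant carries exactly
one first-fail reason; a ranked review table stands in for the manual
curation stage.

**Duo categorization.** Variants passing in both samples are Shared (GBM-S);
a variant passing in only one sample triggers an allele-exact rescue search
in the partner's raw calls (alt ≥ 5 reads and VAF ≥ 5% by default) and is
promoted to Shared on success, otherwise it stays primary-only (GBM-P) or
recurrent-only (GBM-R).

**Oncogenicity classing.** An additive points rubric (catalogue-recurrence
tiers, LoF in a tumor suppressor, predictor consensus, splice disruption,
recurrent oncogene, population-frequency penalty) yields an integer score;
class thresholds are score ≥ 5 → Oncogenic (O), 3–4 → Likely oncogenic (LO),
≤ 2 → VUS.

**Longitudinal metrics.** Per sample, over level-1-passing variants:

- TMR — total mutations, mutations per Mb of a 42 Mb capture, and
  log10(per-Mb); a longitudinal change indicator, *not* clinical TMB;
- MATH = 100 · MAD / median of the VAFs (MAD scaled by 1.4826);
- VAF clonality — 1-D Gaussian mixture by EM (equal- and free-variance
  families, k = 1..5) selected by BIC, plus the per-pair heterogeneity trend
  (MATH recurrent vs primary).

**Synthetic cohorts.** `somaduo.synthetic_cohort` generates paired VCFs,
annotations, a panel and a planted-truth table — trunk/private variants with
clonal VAF structure, flagged FFPE-style C>T artifacts, and high-AF
polymorphisms — and predicts, by independent brute-force enumeration
(`expected_counts`), every audit count and duo tally the pipeline must
reproduce.

## Worked example

```sh
somaduo simulate --seed 7 --out demo/
somaduo report demo/ --pair-id pair1 --seed 7
```

The report step prints the per-category tallies and writes TSVs into
`demo/`. With seed 7:

```
{'GBM-P': {'SUM': 4, 'O': 0, 'LO': 1, 'VUS': 3},
 'GBM-R': {'SUM': 9, 'O': 6, 'LO': 1, 'VUS': 2},
 'GBM-S': {'SUM': 7, 'O': 3, 'LO': 2, 'VUS': 2}}
```

i.e. 4 variants survived the cascade only in the primary sample, 9 only in
the recurrent one, and 7 are shared between the two (each shared variant
counted once). `demo/metrics.tsv` holds the per-sample metrics:

```
sample_id  total_mutations  per_mb  log10_per_mb  math_score  mixture_k  mixture_means
pair1-P    14               0.33    -0.48         40.8        2          0.2516;0.4440
pair1-R    16               0.38    -0.42         28.63       2          0.2962;0.4785
```

Both samples show the two planted VAF clones (mixture_k = 2, means near the
configured clone centers), and MATH decreases from primary to recurrent —
the pair's heterogeneity trend. `demo/recurrent_variants.tsv` lists the O/LO
variants with catalogue count ≥ 15, and `demo/review.tsv` ranks all
assigned variants by score then catalogue count for manual review.

The same operations are available as library calls (`somaduo.process_duo`,
`somaduo.apply_cascade`, `somaduo.fit_vaf_mixture`, ...).

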