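"""VCF/annotation/panel I/O and domain-type invariants."""

from __future__ import annotations

import numpy as np
import pytest

from somaduo.variant_model import (
    MISSING,
    AnnotationBundle,
    GenePanel,
    VariantRecord,
    attach_annotations,
    read_annotations,
    read_gene_panel,
    read_vcf,
    write_annotations,
)

HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="ok">
##FILTER=<ID=strand_bias,Description="sb">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def write_vcf(tmp_path, body, name="x.vcf"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


class TestReadVcf:
    def test_direct_field_mapping(self, tmp_path):
        p = write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP:AD\t0/1:100:80,20\n")
        (rec,) = read_vcf(p, "S1")
        assert rec.total_depth == 100
        assert rec.alt_depth == 20
        assert rec.vaf == pytest.approx(0.20)
        assert rec.caller_flags == frozenset()
        assert rec.pos == 100 and rec.ref == "A" and rec.alt == "G"

    def test_filter_labels_become_caller_flags(self, tmp_path):
        p = write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tstrand_bias\t.\tGT:DP:AD\t0/1:90:60,30\n")
        (rec,) = read_vcf(p, "S1")
        assert rec.caller_flags == frozenset({"strand_bias"})

    def test_triallelic_split_matches_hand_split(self, tmp_path):
        tri = write_vcf(
            tmp_path, "1\t100\t.\tA\tC,T\t.\tPASS\t.\tGT:DP:AD\t0/1:100:60,25,15\n", "tri.vcf"
        )
        two = write_vcf(
            tmp_path,
            "1\t100\t.\tA\tC\t.\tPASS\t.\tGT:DP:AD\t0/1:100:60,25\n"
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP:AD\t0/1:100:60,15\n",
            "two.vcf",
        )
        split = read_vcf(tri, "S1")
        hand = read_vcf(two, "S1")
        assert [(r.key, r.total_depth, r.alt_depth) for r in split] == [
            (r.key, r.total_depth, r.alt_depth) for r in hand
        ]

    def test_multiallelic_split_conserves_alt_alleles(self, tmp_path):
        body = (
            "1\t100\t.\tA\tC,T\t.\tPASS\t.\tGT:DP:AD\t0/1:100:60,25,15\n"
            "1\t200\t.\tG\tA\t.\tPASS\t.\tGT:DP:AD\t0/1:80:50,30\n"
            "1\t300\t.\tC\tA,G,T\t.\tPASS\t.\tGT:DP:AD\t0/1:120:60,20,20,20\n"
        )
        recs = read_vcf(write_vcf(tmp_path, body), "S1")
        assert len(recs) == 2 + 1 + 3  # one record per ALT allele

    def test_missing_depth_fields_is_hard_error(self, tmp_path):
        p = write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="DP or AD"):
            read_vcf(p, "S1")

    def test_vaf_recomputed_from_allelic_depths(self, tmp_path):
        body = "".join(
            f"1\t{100 + i}\t.\tA\tG\t.\tPASS\t.\tGT:DP:AD\t0/1:{d}:{d - a},{a}\n"
            for i, (d, a) in enumerate([(50, 7), (173, 99), (60, 0), (200, 200)])
        )
        for rec in read_vcf(write_vcf(tmp_path, body), "S1"):
            assert abs(rec.vaf - rec.alt_depth / rec.total_depth) < 1e-9


class TestVariantRecord:
    def test_alt_depth_bounds_enforced(self):
        with pytest.raises(ValueError):
            VariantRecord("S", "1", 1, "A", "G", total_depth=10, alt_depth=11)

    def test_sequences_upper_cased(self):
        r = VariantRecord("S", "1", 1, "a", "g", 10, 5)
        assert (r.ref, r.alt) == ("A", "G")


class TestAnnotations:
    def test_round_trip_of_synthetic_table(self, tmp_path, bundle_factory):
        rng = np.random.default_rng(5)
        bundles = {}
        for i in range(50):
            bundles[("7", 1000 + i, "A", "G")] = bundle_factory(
                damaging=int(rng.integers(0, 7)),
                cosmic_count=int(rng.integers(0, 200)),
                cosmic_ids=("COSM%d" % i,) if i % 3 else (),
                af_1kg=None if i % 2 else float(rng.uniform(0, 0.5)),
            )
        path = tmp_path / "ann.tsv"
        write_annotations(bundles, path)
        assert read_annotations(path) == bundles

    def test_empty_cell_is_missing_and_bool_parsing(self, tmp_path, bundle_factory):
        path = tmp_path / "ann.tsv"
        write_annotations(
            {("1", 5, "A", "G"): bundle_factory(af_1kg=None, dbsnp_common=True)}, path
        )
        b = read_annotations(path)[("1", 5, "A", "G")]
        assert b.af_1kg is MISSING
        assert b.dbsnp_common is True

    def test_unknown_enum_string_errors(self, tmp_path, bundle_factory):
        path = tmp_path / "ann.tsv"
        write_annotations({("1", 5, "A", "G"): bundle_factory()}, path)
        bad = path.read_text().replace("missense", "nonsense_enum")
        path.write_text(bad)
        with pytest.raises(ValueError, match="nonsense_enum"):
            read_annotations(path)

    def test_duplicate_keys_error(self, tmp_path, bundle_factory):
        path = tmp_path / "ann.tsv"
        write_annotations({("1", 5, "A", "G"): bundle_factory()}, path)
        lines = path.read_text().rstrip("\n").split("\n")
        path.write_text("\n".join(lines + [lines[-1]]) + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_annotations(path)

    def test_missing_distinct_from_zero(self):
        assert AnnotationBundle(af_1kg=0.0).af_1kg is not MISSING
        assert AnnotationBundle(af_1kg=None).af_1kg is MISSING


class TestAttachAnnotations:
    def test_left_join_preserves_record_set(self, record_factory, bundle_factory):
        records = [record_factory(pos=p) for p in range(1, 11)]
        bundles = {r.key: bundle_factory(gene=f"G{r.pos}") for r in records[:7]}
        out = attach_annotations(records, bundles)
        assert len(out) == 10
        assert [r.key for r in out] == [r.key for r in records]
        assert sum(1 for r in out if r.annotations.gene.startswith("G")) == 7
        # unmatched records carry the default (all-MISSING) policy
        assert all(r.annotations.effect.value == "none" for r in out[7:])

    def test_key_matching_is_allele_exact(self, record_factory, bundle_factory):
        rec = record_factory()  # C>T at 17:1000
        bundle_other_alt = {("17", 1000, "C", "G"): bundle_factory(gene="WRONG")}
        (out,) = attach_annotations([rec], bundle_other_alt)
        assert out.annotations.gene != "WRONG"


class TestGenePanel:
    def test_dedup_and_case_normalization(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("TP53\nPTEN\ntp53\n# comment\n\n")
        panel = read_gene_panel(p)
        assert len(panel) == 2
        assert "tp53" in panel and "PTEN" in panel

    def test_blank_file_errors(self, tmp_path):
        p = tmp_path / "panel.txt"
        p.write_text("\n\n# only comments\n")
        with pytest.raises(ValueError):
            read_gene_panel(p)

    def test_empty_symbol_set_rejected(self):
        with pytest.raises(ValueError):
            GenePanel(symbols=frozenset())
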