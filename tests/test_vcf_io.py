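"""VCF/BED ingestion, output round-trips, merge and intersect semantics."""

import numpy as np
import pytest

from rnatmb import (
    Callset,
    ContractError,
    RegionSet,
    VcfFormatError,
    intersect_callsets,
    merge_callsets,
    read_callset,
    read_regions,
    write_callset,
    write_regions,
)
from rnatmb.vcf_io import normalize_chrom

from conftest import make_callset, make_variant, random_callset, write_vcf


class TestReadCallset:
    def test_multiallelic_alt_excluded_and_counted(self, tmp_path):
        path = write_vcf(
            tmp_path / "a.vcf",
            [
                ["chr1", 100, ".", "C", "T", ".", "PASS", "TLOD=6.3", "GT:AD", "0/1:10,5"],
                ["chr1", 200, ".", "A", "G,C", ".", "PASS", ".", "GT:AD", "0/1:10,5"],
            ],
        )
        callset = read_callset(path, "rnaseq_tumor_only")
        assert len(callset) == 1
        assert callset.multiallelic_excluded == 1
        assert callset.variants[0].key == ("chr1", 100, "C", "T")

    def test_split_biallelic_lines_at_one_site_excluded(self, tmp_path):
        # a tri-allelic site encoded as two biallelic lines is still dropped
        path = write_vcf(
            tmp_path / "a.vcf",
            [
                ["chr1", 200, ".", "A", "G", ".", "PASS", ".", "GT:AD", "0/1:8,2"],
                ["chr1", 200, ".", "A", "C", ".", "PASS", ".", "GT:AD", "0/1:8,2"],
                ["chr1", 300, ".", "G", "T", ".", "PASS", ".", "GT:AD", "0/1:8,2"],
            ],
        )
        callset = read_callset(path, "rnaseq_tumor_only")
        assert len(callset) == 1
        assert callset.multiallelic_excluded == 2

    def test_retained_plus_excluded_equals_total(self, tmp_path):
        rows = [
            ["chr1", 100, ".", "C", "T", ".", "PASS", ".", "GT:AD", "0/1:9,1"],
            ["chr1", 150, ".", "A", "G,C", ".", "PASS", ".", "GT:AD", "0/1:9,1"],
            ["chr1", 200, ".", "A", "G", ".", "PASS", ".", "GT:AD", "0/1:9,1"],
            ["chr1", 200, ".", "A", "C", ".", "PASS", ".", "GT:AD", "0/1:9,1"],
        ]
        callset = read_callset(
            write_vcf(tmp_path / "a.vcf", rows), "rnaseq_tumor_only"
        )
        assert len(callset) + callset.multiallelic_excluded == len(rows)

    def test_empty_vcf(self, tmp_path):
        callset = read_callset(write_vcf(tmp_path / "e.vcf", []), "wes_matched")
        assert len(callset) == 0

    def test_filter_labels_semicolon_split(self, tmp_path):
        path = write_vcf(
            tmp_path / "f.vcf",
            [["chr1", 100, ".", "C", "T", ".", "germline_risk;panel_of_normals",
              ".", "GT:AD", "0/1:5,5"]],
        )
        v = read_callset(path, "rnaseq_tumor_only").variants[0]
        assert v.filter_labels == {"germline_risk", "panel_of_normals"}

    @pytest.mark.parametrize("filter_field", [".", "PASS"])
    def test_dot_and_pass_both_mean_unfiltered(self, tmp_path, filter_field):
        path = write_vcf(
            tmp_path / "p.vcf",
            [["chr1", 100, ".", "C", "T", ".", filter_field, ".", "GT:AD", "0/1:5,5"]],
        )
        v = read_callset(path, "rnaseq_tumor_only").variants[0]
        assert v.filter_labels == frozenset()
        assert v.is_pass

    def test_missing_info_is_absent_not_zero(self, tmp_path):
        path = write_vcf(
            tmp_path / "m.vcf",
            [["chr1", 100, ".", "C", "T", ".", "PASS", "ECNT=2", "GT:AD", "0/1:5,5"]],
        )
        v = read_callset(path, "rnaseq_tumor_only").variants[0]
        assert "TLOD" not in v.caller_info
        assert v.exac_nontcga_all is None
        assert v.caller_info["ECNT"] == 2

    def test_pass_through_of_planted_fields(self, tmp_path):
        path = write_vcf(
            tmp_path / "t.vcf",
            [["chr1", 100, "rs42", "C", "T", ".", "PASS",
              "TLOD=6.3;ExAC_nontcga_ALL=0.25;dbSNP150_ID=rs42", "GT:AD", "0/1:10,5"]],
        )
        v = read_callset(path, "rnaseq_tumor_only").variants[0]
        assert v.caller_info["TLOD"] == pytest.approx(6.3)
        assert v.exac_nontcga_all == pytest.approx(0.25)
        assert v.in_dbsnp and v.rsid == "rs42"
        assert (v.ad_ref, v.ad_alt) == (10, 5)

    def test_chromosome_name_normalized(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=1,length=248956422>\n"
            "##FORMAT=<ID=GT,Number=1,Type=String,Description=\"g\">\n"
        )
        path = write_vcf(
            tmp_path / "n.vcf",
            [["1", 100, ".", "C", "T", ".", ".", ".", "GT", "0/1"]],
            header=header,
        )
        assert read_callset(path, "wes_matched").variants[0].chrom == "chr1"
        assert normalize_chrom("chrX") == "chrX"

    def test_zero_samples_rejected(self, tmp_path):
        path = tmp_path / "z.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with pytest.raises(VcfFormatError, match="zero sample"):
            read_callset(path, "wes_matched")

    def test_garbage_file_rejected(self, tmp_path):
        path = tmp_path / "g.vcf"
        path.write_text("not a vcf at all\n")
        with pytest.raises(VcfFormatError):
            read_callset(path, "wes_matched")

    def test_unknown_source_tag(self, tmp_path):
        path = write_vcf(tmp_path / "s.vcf", [])
        with pytest.raises(ContractError, match="source"):
            read_callset(path, "exome")


class TestRoundTrip:
    def test_write_read_preserves_downstream_fields(self, small_cohort, tmp_path):
        original = read_callset(
            small_cohort.rnaseq_paths["S001"], "rnaseq_tumor_only"
        )
        rewritten = read_callset(
            write_callset(original, tmp_path / "rt.vcf"), "rnaseq_tumor_only"
        )
        assert len(rewritten) == len(original)
        for a, b in zip(original.variants, rewritten.variants):
            assert a.key == b.key
            assert a.filter_labels == b.filter_labels
            assert a.rsid == b.rsid
            assert (a.ad_ref, a.ad_alt) == (b.ad_ref, b.ad_alt)
            assert set(a.caller_info) == set(b.caller_info)
            for field in a.caller_info:
                assert a.caller_info[field] == pytest.approx(
                    b.caller_info[field], abs=1e-4
                ), field
            if a.exac_nontcga_all is None:
                assert b.exac_nontcga_all is None
            else:
                assert b.exac_nontcga_all == pytest.approx(
                    a.exac_nontcga_all, rel=1e-5
                )
            assert a.in_dbsnp == b.in_dbsnp


class TestMerge:
    def test_size_additivity(self):
        a = make_callset([make_variant(pos=p, sample_id="A") for p in (1, 2, 3)],
                         sample_id="A")
        b = make_callset([make_variant(pos=p, sample_id="B") for p in (4, 5, 6, 7)],
                         sample_id="B")
        assert len(merge_callsets([a, b])) == 7

    def test_single_merge_is_identity(self):
        a = make_callset([make_variant(pos=5)])
        merged = merge_callsets([a])
        assert [v.key for v in merged] == [v.key for v in a]
        assert merged.sample_id == a.sample_id

    def test_same_key_two_samples_keeps_both_origins(self):
        a = make_callset([make_variant(pos=9, sample_id="A")], sample_id="A")
        b = make_callset([make_variant(pos=9, sample_id="B")], sample_id="B")
        merged = merge_callsets([a, b])
        assert len(merged) == 2
        assert {v.sample_id for v in merged} == {"A", "B"}

    def test_mixed_sources_rejected(self):
        a = make_callset([make_variant()], source="rnaseq_tumor_only")
        b = make_callset([make_variant()], source="wes_matched")
        with pytest.raises(ContractError, match="mixed"):
            merge_callsets([a, b])


class TestIntersect:
    def test_self_intersection_identity(self):
        rng = np.random.default_rng(1)
        a = random_callset(rng, 50)
        assert intersect_callsets(a, a, "full_key").keys() == a.keys()

    def test_allele_mismatch_modes(self):
        a = make_callset([make_variant(pos=100, ref="C", alt="T")])
        b = make_callset([make_variant(pos=100, ref="C", alt="A")])
        assert len(intersect_callsets(a, b, "full_key")) == 0
        assert len(intersect_callsets(a, b, "coordinate_only")) == 1

    def test_empty_reference(self):
        a = make_callset([make_variant()])
        b = make_callset([])
        assert len(intersect_callsets(a, b, "full_key")) == 0

    @pytest.mark.parametrize("mode", ["full_key", "coordinate_only"])
    def test_idempotent_and_bounded(self, mode):
        rng = np.random.default_rng(2)
        a, b = random_callset(rng, 80), random_callset(rng, 80)
        once = intersect_callsets(a, b, mode)
        twice = intersect_callsets(once, b, mode)
        assert [v.key for v in twice] == [v.key for v in once]
        assert len(once) <= len(a)

    def test_full_key_never_larger_than_coordinate_only(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = random_callset(rng, 60), random_callset(rng, 60)
            assert len(intersect_callsets(a, b, "full_key")) <= len(
                intersect_callsets(a, b, "coordinate_only")
            )

    def test_unknown_mode(self):
        a = make_callset([])
        with pytest.raises(ContractError, match="match_mode"):
            intersect_callsets(a, a, "fuzzy")


class TestRegions:
    def test_single_interval_megabases(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t3000000\n")
        assert read_regions(bed).total_megabases == pytest.approx(3.0)

    def test_overlap_merged(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t0\t100\nchr1\t50\t200\n")
        regions = read_regions(bed)
        assert regions.total_bases == 200
        assert len(regions) == 1

    def test_empty_bed_refused_downstream(self, tmp_path):
        from rnatmb import compute_tmb
        from conftest import make_callset

        bed = tmp_path / "e.bed"
        bed.write_text("")
        regions = read_regions(bed)
        assert regions.total_megabases == 0
        with pytest.raises(ContractError, match="denominator"):
            compute_tmb(make_callset([]), regions, "rule")

    def test_inverted_interval_names_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t10\t100\nchr2\t500\t400\n")
        with pytest.raises(VcfFormatError, match="2"):
            read_regions(bed)

    def test_contains_half_open_boundaries(self):
        regions = RegionSet([("chr1", 100, 200)])
        assert not regions.contains("chr1", 100)  # 1-based pos 100 = 0-based 99
        assert regions.contains("chr1", 101)
        assert regions.contains("chr1", 200)
        assert not regions.contains("chr1", 201)
        assert not regions.contains("chr2", 150)

    def test_write_read_round_trip(self, tmp_path):
        regions = RegionSet([("chr2", 10, 500), ("chr1", 0, 100)])
        back = read_regions(write_regions(regions, tmp_path / "w.bed"))
        assert back.intervals == regions.intervals
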