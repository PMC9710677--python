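"""Tests for region loading, read iteration, and the two scan modes."""

from __future__ import annotations

import pysam
import pytest

from telotally.fixtures import FixtureSpec, generate_fixture
from telotally.motifs import build_motif_spec
from telotally.scan import (
    GenomicRegion,
    InputFileError,
    ReadFilterPolicy,
    RegionError,
    RegionSet,
    full_scan,
    iterate_region_reads,
    iterate_unmapped,
    load_regions,
    regions_from_bed,
    scan,
)

from conftest import make_bam

TELO = ("TTAGGG" * 17)[:100]
BACKGROUND = (
    "ACGTACTGACTGATCGATCGATTACGCTAGCTAGCATCGATCGTACGATCGATCATGCTAGC"
    "TACGATCGATCGTACGTAGCATCGATCGATCGTACGAT"
)[:100]


class TestRegionLoading:
    def test_direct_parse(self):
        rs = load_regions([("chr1_tel", "chr1", 1, 10_000)])
        assert len(rs) == 1
        assert rs[0] == GenomicRegion("chr1", 1, 10_000, "chr1_tel")

    def test_empty_entries_error(self):
        with pytest.raises(RegionError, match="no regions"):
            load_regions([])

    def test_returned_sorted(self):
        rs = load_regions(
            [
                ("b", "chr2", 5, 10),
                ("a", "chr1", 100, 200),
                ("c", "chr1", 1, 50),
            ]
        )
        assert [r.label for r in rs] == ["c", "a", "b"]

    def test_duplicate_labels_rejected(self):
        with pytest.raises(RegionError, match="duplicate"):
            load_regions([("x", "chr1", 1, 10), ("x", "chr2", 1, 10)])

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(RegionError):
            GenomicRegion("chr1", 0, 10, "bad_start")
        with pytest.raises(RegionError):
            GenomicRegion("chr1", 10, 9, "end_before_start")

    def test_bed_conversion_to_1_based_inclusive(self, tmp_path):
        bed = tmp_path / "regions.bed"
        bed.write_text("chr1\t0\t10000\tchr1_tel\nchr2\t500\t600\n")
        rs = regions_from_bed(str(bed))
        assert rs[0] == GenomicRegion("chr1", 1, 10_000, "chr1_tel")
        assert rs[1].start == 501 and rs[1].end == 600


class TestReadIteration:
    def test_duplicates_filtered_not_yielded(self, tmp_path):
        reads = [
            {"qname": f"r{i}", "seq": TELO, "chrom": "chr1", "pos1": 100 + 200 * i}
            for i in range(4)
        ]
        reads.append(
            {"qname": "dup", "seq": TELO, "chrom": "chr1", "pos1": 100, "flag": 0x400}
        )
        bam_path = make_bam(tmp_path, reads)
        region = GenomicRegion("chr1", 1, 10_000, "tel")
        from telotally.scan import CategoryTally

        stats = CategoryTally()
        with pysam.AlignmentFile(bam_path) as bam:
            yielded = list(
                iterate_region_reads(bam, region, ReadFilterPolicy.default(), stats)
            )
        assert len(yielded) == 4
        assert stats.filtered == 1

    def test_empty_region_yields_nothing(self, tmp_path):
        bam_path = make_bam(
            tmp_path, [{"qname": "r0", "seq": TELO, "chrom": "chr1", "pos1": 50_000}]
        )
        region = GenomicRegion("chr2", 1, 10_000, "empty")
        with pysam.AlignmentFile(bam_path) as bam:
            assert list(
                iterate_region_reads(bam, region, ReadFilterPolicy.default())
            ) == []

    def test_boundary_spanning_read_yielded(self, tmp_path):
        # starts inside the region, ends outside: still overlaps by >= 1 base
        bam_path = make_bam(
            tmp_path,
            [{"qname": "edge", "seq": TELO, "chrom": "chr1", "pos1": 9_990}],
        )
        region = GenomicRegion("chr1", 1, 10_000, "tel")
        with pysam.AlignmentFile(bam_path) as bam:
            yielded = list(
                iterate_region_reads(bam, region, ReadFilterPolicy.default())
            )
        assert [r.query_name for r in yielded] == ["edge"]

    def test_unmapped_iteration_and_filtering(self, tmp_path):
        reads = [
            {"qname": "u1", "seq": TELO, "flag": 0x4},
            {"qname": "u2", "seq": BACKGROUND, "flag": 0x4},
            {"qname": "u3", "seq": TELO, "flag": 0x4},
            {"qname": "udup", "seq": TELO, "flag": 0x4 | 0x400},
            {"qname": "mapped", "seq": TELO, "chrom": "chr1", "pos1": 100},
        ]
        bam_path = make_bam(tmp_path, reads)
        with pysam.AlignmentFile(bam_path) as bam:
            yielded = list(iterate_unmapped(bam, ReadFilterPolicy.default()))
        assert sorted(r.query_name for r in yielded) == ["u1", "u2", "u3"]

    def test_placed_unmapped_owned_by_unmapped_stream(self, tmp_path):
        # an unmapped mate stored with its mapped mate's coordinate, inside
        # an include region
        reads = [
            {"qname": "mate", "seq": TELO, "chrom": "chr1", "pos1": 500, "flag": 0x4},
            {"qname": "mapped", "seq": TELO, "chrom": "chr1", "pos1": 500},
        ]
        bam_path = make_bam(tmp_path, reads)
        region = GenomicRegion("chr1", 1, 10_000, "tel")
        policy = ReadFilterPolicy.default()
        with pysam.AlignmentFile(bam_path) as bam:
            from_region = [r.query_name for r in iterate_region_reads(bam, region, policy)]
            from_unmapped = [r.query_name for r in iterate_unmapped(bam, policy)]
        assert from_region == ["mapped"]
        assert from_unmapped == ["mate"]

    def test_missing_index_reports_actionable_error(self, tmp_path):
        bam_path = make_bam(
            tmp_path, [{"qname": "r", "seq": TELO, "chrom": "chr1", "pos1": 100}]
        )
        import os

        os.remove(bam_path + ".bai")
        region = GenomicRegion("chr1", 1, 10_000, "tel")
        with pysam.AlignmentFile(bam_path) as bam:
            with pytest.raises(InputFileError, match="index"):
                list(iterate_region_reads(bam, region, ReadFilterPolicy.default()))

    def test_unknown_chromosome_names_available_ones(self, tmp_path):
        bam_path = make_bam(
            tmp_path, [{"qname": "r", "seq": TELO, "chrom": "chr1", "pos1": 100}]
        )
        region = GenomicRegion("chrMT", 1, 10, "bad")
        with pysam.AlignmentFile(bam_path) as bam:
            with pytest.raises(InputFileError, match="chr1"):
                list(iterate_region_reads(bam, region, ReadFilterPolicy.default()))


class TestScan:
    def test_planted_truth_recovery(self, tmp_path):
        spec = FixtureSpec(
            seed=3,
            n_forward=6,
            n_reverse=4,
            n_background=20,
            n_unmapped_telomeric=4,
        )
        bam_path, truth = generate_fixture(spec, str(tmp_path))
        report = scan(bam_path, load_regions(spec.include_regions))
        assert report.categories["includes"].stage2_passes == 10
        assert report.categories["unmapped"].stage2_passes == 4
        assert report.telomeric_read_count == 14
        for cat in ("includes", "unmapped"):
            assert report.categories[cat].to_dict() == truth.expected[cat]

    def test_region_mode_has_no_genomic_category(self, tmp_path):
        spec = FixtureSpec(seed=4, n_forward=2, n_genomic_telomeric=2)
        bam_path, _ = generate_fixture(spec, str(tmp_path))
        report = scan(bam_path, load_regions(spec.include_regions))
        assert report.mode == "regions"
        assert "genomic" not in report.categories

    def test_worker_counts_give_identical_reports(self, tmp_path):
        spec = FixtureSpec(
            seed=5, n_forward=8, n_reverse=5, n_background=15, n_unmapped_telomeric=3
        )
        bam_path, _ = generate_fixture(spec, str(tmp_path))
        regions = load_regions(spec.include_regions)
        reports = [
            scan(bam_path, regions, workers=w).to_dict() for w in (1, 2, 4)
        ]
        assert reports[0] == reports[1] == reports[2]

    def test_overlapping_regions_count_read_once(self, tmp_path):
        reads = [
            {"qname": "inboth", "seq": TELO, "chrom": "chr1", "pos1": 950},
            {"qname": "infirst", "seq": TELO, "chrom": "chr1", "pos1": 100},
        ]
        bam_path = make_bam(tmp_path, reads)
        regions = load_regions(
            [("left", "chr1", 1, 1_000), ("right", "chr1", 900, 2_000)]
        )
        report = scan(bam_path, regions)
        assert report.categories["includes"].stage2_passes == 2
        # the overlap read is attributed to the first region in sorted order
        by_label = {rt.region.label: rt.tally for rt in report.regions}
        assert by_label["left"].stage2_passes == 2
        assert by_label["right"].stage2_passes == 0

    def test_full_scan_populates_genomic_category(self, tmp_path):
        spec = FixtureSpec(seed=6, n_forward=3, n_genomic_telomeric=2)
        bam_path, truth = generate_fixture(spec, str(tmp_path))
        report = full_scan(bam_path, load_regions(spec.include_regions))
        assert report.mode == "full"
        assert report.categories["genomic"].stage2_passes == 2
        for cat in ("includes", "unmapped", "genomic"):
            assert report.categories[cat].to_dict() == truth.expected[cat]

    def test_empty_bam_all_tallies_zero(self, tmp_path):
        bam_path = make_bam(tmp_path, [])
        regions = load_regions([("tel", "chr1", 1, 10_000)])
        report = full_scan(bam_path, regions)
        assert report.total_examined == 0
        assert all(t.examined == 0 for t in report.categories.values())

    def test_region_mode_equals_full_scan_restriction(self, tmp_path):
        spec = FixtureSpec(
            seed=7,
            n_forward=5,
            n_reverse=3,
            n_degenerate=2,
            n_near_miss=3,
            n_background=10,
            n_genomic_telomeric=2,
            n_unmapped_telomeric=3,
            n_duplicate_telomeric=2,
            n_placed_unmapped_telomeric=1,
        )
        bam_path, _ = generate_fixture(spec, str(tmp_path))
        regions = load_regions(spec.include_regions)
        fast = scan(bam_path, regions)
        full = full_scan(bam_path, regions)
        for cat in ("includes", "unmapped"):
            assert fast.categories[cat].to_dict() == full.categories[cat].to_dict()
        assert [rt.to_dict() for rt in fast.regions] == [
            rt.to_dict() for rt in full.regions
        ]

    def test_monotonicity_one_extra_read_one_extra_count(self, tmp_path):
        base = FixtureSpec(seed=8, n_forward=5, n_background=10)
        plus = FixtureSpec(seed=8, n_forward=6, n_background=10)
        bam_a, _ = generate_fixture(base, str(tmp_path / "a"))
        bam_b, _ = generate_fixture(plus, str(tmp_path / "b"))
        regions = load_regions(base.include_regions)
        a = scan(bam_a, regions).categories["includes"].stage2_passes
        b = scan(bam_b, regions).categories["includes"].stage2_passes
        assert b == a + 1

    def test_tally_ordering_invariants(self, tmp_path):
        spec = FixtureSpec(
            seed=9, n_forward=4, n_near_miss=3, n_background=8, n_unmapped_telomeric=2
        )
        bam_path, _ = generate_fixture(spec, str(tmp_path))
        report = scan(bam_path, load_regions(spec.include_regions))
        for tally in list(report.categories.values()) + [
            rt.tally for rt in report.regions
        ]:
            assert tally.stage2_passes <= tally.stage1_passes <= tally.examined
        assert sum(rt.tally.stage2_passes for rt in report.regions) == (
            report.categories["includes"].stage2_passes
        )

    def test_policy_switches_are_honoured(self, tmp_path):
        reads = [
            {"qname": "ok", "seq": TELO, "chrom": "chr1", "pos1": 100},
            {"qname": "dup", "seq": TELO, "chrom": "chr1", "pos1": 100, "flag": 0x400},
        ]
        bam_path = make_bam(tmp_path, reads)
        regions = load_regions([("tel", "chr1", 1, 10_000)])
        keep_dups = ReadFilterPolicy(
            exclude_duplicates=False,
            exclude_secondary=True,
            exclude_supplementary=True,
            exclude_qcfail=True,
        )
        spec = build_motif_spec()
        strict = scan(bam_path, regions, spec, ReadFilterPolicy.default())
        loose = scan(bam_path, regions, spec, keep_dups)
        assert strict.categories["includes"].stage2_passes == 1
        assert loose.categories["includes"].stage2_passes == 2

    def test_motif_variant_tally(self, tmp_path):
        bam_path = make_bam(
            tmp_path,
            [{"qname": "r", "seq": "TTAGGG" * 3, "chrom": "chr1", "pos1": 100}],
        )
        report = scan(bam_path, load_regions([("tel", "chr1", 1, 10_000)]))
        assert report.motif_variants == {"TTAGGG": 3}
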