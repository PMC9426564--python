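import numpy as np
import pytest

from coamag.coverage_profiles import (AlignmentInterval, contig_depth_table,
                                      detect_genome, genome_coverage,
                                      load_alignments, prevalence_abundance,
                                      write_alignment_tsv)
from coamag.io_formats import write_depth_table, read_depth_table


def iv(target, start, end, sample="s1", query="q", mapq=60, primary=True):
    return AlignmentInterval(query_id=query, target_id=target, start=start,
                             end=end, sample_id=sample, is_primary=primary, mapq=mapq)


def perbase_oracle(intervals, length, sample):
    """Naive per-base coverage array for one target and sample."""
    cov = np.zeros(length)
    for i in intervals:
        if i.sample_id == sample:
            cov[i.start:i.end] += 1
    return cov


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:c1\tLN:2000\n"


class TestLoadAlignments:
    def test_sam_coordinates_are_half_open(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(SAM_HEADER + "r1\t0\tc1\t1\t60\t100M\t*\t0\t0\t*\t*\n")
        (got,) = load_alignments(sam, sample_id="s1")
        assert (got.start, got.end) == (0, 100)

    def test_secondary_dropped_when_primary_only(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(SAM_HEADER
                       + "r1\t0\tc1\t1\t60\t50M\t*\t0\t0\t*\t*\n"
                       + "r1\t256\tc1\t101\t60\t50M\t*\t0\t0\t*\t*\n")
        got = list(load_alignments(sam, sample_id="s1"))
        assert len(got) == 1
        got = list(load_alignments(sam, sample_id="s1", primary_only=False))
        assert len(got) == 2

    def test_mapq_filter(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(SAM_HEADER + "r1\t0\tc1\t1\t5\t50M\t*\t0\t0\t*\t*\n")
        assert list(load_alignments(sam, sample_id="s1", mapq_min=10)) == []

    def test_tsv_equals_sam_for_same_alignment(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(SAM_HEADER + "r1\t0\tc1\t11\t60\t40M\t*\t0\t0\t*\t*\n")
        (from_sam,) = load_alignments(sam, sample_id="s1")
        tsv = tmp_path / "a.tsv"
        write_alignment_tsv([from_sam], tsv)
        (from_tsv,) = load_alignments(tsv, sample_id="s1")
        assert (from_tsv.query_id, from_tsv.target_id, from_tsv.start, from_tsv.end) == \
            (from_sam.query_id, from_sam.target_id, from_sam.start, from_sam.end)

    def test_interval_beyond_target_length_rejected(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:c1\tLN:50\n"
                       + "r1\t0\tc1\t31\t60\t40M\t*\t0\t0\t*\t*\n")
        with pytest.raises(ValueError, match="c1"):
            list(load_alignments(sam, sample_id="s1"))


class TestContigDepthTable:
    def test_single_read_depth_matches_perbase_oracle(self):
        intervals = [iv("c1", 0, 50)]
        table = contig_depth_table(intervals, {"c1": 2000}, ["s1"])
        cov = perbase_oracle(intervals, 2000, "s1")
        assert table.mean_depth[0, 0] == pytest.approx(cov.mean())
        assert table.mean_depth[0, 0] == pytest.approx(50 / 2000)
        assert table.depth_variance[0, 0] == pytest.approx(cov.var())

    def test_short_contigs_excluded(self):
        intervals = [iv("short", 0, 100), iv("long", 0, 100)]
        table = contig_depth_table(intervals, {"short": 1000, "long": 1500}, ["s1"])
        assert [c for c, _ in table.contigs] == ["long"]

    def test_no_alignments_zero_rows(self):
        table = contig_depth_table([], {"c1": 2000, "c2": 1600}, ["s1", "s2"])
        assert np.all(table.mean_depth == 0)
        assert np.all(table.depth_variance == 0)

    def test_randomized_against_perbase_oracle(self, rng):
        contigs = {f"c{i}": int(rng.integers(1500, 3000)) for i in range(10)}
        samples = [f"s{i}" for i in range(3)]
        intervals = []
        for _ in range(300):
            c = rng.choice(list(contigs))
            L = contigs[c]
            start = int(rng.integers(0, L - 10))
            end = int(rng.integers(start + 1, min(start + 120, L) + 1))
            intervals.append(iv(c, start, end, sample=str(rng.choice(samples)),
                                query=f"q{rng.integers(1e6)}"))
        table = contig_depth_table(intervals, contigs, samples)
        for i, (c, L) in enumerate(table.contigs):
            for j, s in enumerate(samples):
                cov = perbase_oracle([x for x in intervals if x.target_id == c], L, s)
                assert table.mean_depth[i, j] == pytest.approx(cov.mean(), abs=1e-9)
                assert table.depth_variance[i, j] == pytest.approx(cov.var(), abs=1e-9)

    def test_split_then_merge_equals_single_pass(self, rng):
        intervals = [iv("c1", int(s), int(s) + 40, query=f"q{n}")
                     for n, s in enumerate(rng.integers(0, 1900, size=60))]
        whole = contig_depth_table(intervals, {"c1": 2000}, ["s1"])
        merged = contig_depth_table(intervals[:30] + intervals[30:], {"c1": 2000}, ["s1"])
        assert whole.equals(merged)

    def test_writer_total_equals_row_sum(self, tmp_path, rng):
        intervals = [iv("c1", 0, 100), iv("c1", 50, 150, sample="s2")]
        table = contig_depth_table(intervals, {"c1": 2000}, ["s1", "s2"])
        path = tmp_path / "depth.tsv"
        write_depth_table(table, path)
        got = read_depth_table(path)
        assert got.total_avg_depth[0] == pytest.approx(table.mean_depth[0].sum())


class TestGenomeCoverage:
    def test_overlap_counted_once_in_breadth(self):
        intervals = [iv("g1", 0, 100, query="q1"), iv("g1", 50, 150, query="q2")]
        (cov,) = genome_coverage(intervals, {"g1": 300}, {"s1": 10})
        assert cov.breadth == pytest.approx(150 / 300)
        assert cov.mean_depth == pytest.approx(200 / 300)
        assert cov.mapped_read_fraction == pytest.approx(2 / 10)

    def test_full_tiling_breadth_one(self):
        intervals = [iv("g1", i * 100, (i + 1) * 100, query=f"q{i}") for i in range(3)]
        (cov,) = genome_coverage(intervals, {"g1": 300}, {"s1": 3})
        assert cov.breadth == 1.0

    def test_no_reads_all_zero(self):
        (cov,) = genome_coverage([], {"g1": 300}, {"s1": 5})
        assert (cov.breadth, cov.mean_depth, cov.mapped_read_fraction) == (0.0, 0.0, 0.0)

    def test_duplicate_query_counts_once_for_fraction_twice_for_depth(self):
        intervals = [iv("g1", 0, 100, query="q1"), iv("g1", 100, 200, query="q1")]
        (cov,) = genome_coverage(intervals, {"g1": 400}, {"s1": 10})
        assert cov.mapped_read_fraction == pytest.approx(1 / 10)
        assert cov.mean_depth == pytest.approx(200 / 400)

    def test_breadth_monotone_as_alignments_added(self, rng):
        base = []
        prev = 0.0
        for n in range(20):
            start = int(rng.integers(0, 900))
            base.append(iv("g1", start, start + 100, query=f"q{n}"))
            (cov,) = genome_coverage(base, {"g1": 1000}, {"s1": 100})
            assert cov.breadth >= prev
            prev = cov.breadth

    def test_zero_length_genome_rejected(self):
        with pytest.raises(ValueError):
            genome_coverage([], {"g1": 0}, {"s1": 5})


class TestDetectionPrevalence:
    @pytest.mark.parametrize("breadth,expected", [(0.31, True), (0.30, True), (0.29, False)])
    def test_detection_threshold_inclusive(self, breadth, expected):
        from coamag.coverage_profiles import GenomeCoverage

        cov = GenomeCoverage("g", "s", breadth=breadth, mean_depth=1.0,
                             mapped_read_fraction=0.1)
        assert detect_genome(cov) is expected

    def test_prevalence_counts_detected_samples(self):
        from coamag.coverage_profiles import GenomeCoverage

        covs = [GenomeCoverage("g", f"s{i}", breadth=b, mean_depth=1.0,
                               mapped_read_fraction=0.0)
                for i, b in enumerate([0.5, 0.4, 0.31, 0.1, 0.0])]
        (pa,) = prevalence_abundance(covs, {"g": 1000})
        assert pa.prevalence == 3

    def test_cumulative_abundance_formula(self):
        from coamag.coverage_profiles import GenomeCoverage

        covs = [GenomeCoverage("g", "s1", 0.9, 1.0, 0.02),
                GenomeCoverage("g", "s2", 0.9, 1.0, 0.01)]
        (pa,) = prevalence_abundance(covs, {"g": 2_000_000})
        assert pa.cumulative_abundance == pytest.approx((2 + 1) / 2e6)

    def test_absent_genome_zeroes(self):
        (pa,) = prevalence_abundance([], {"g": 1000})
        assert (pa.prevalence, pa.cumulative_abundance) == (0, 0.0)
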