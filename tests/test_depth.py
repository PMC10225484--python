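"""Binned depth extraction, coverage baselining and IQR outlier screening."""

import io

import numpy as np
import pytest

from rdcnv.depth import (
    CoverageSummary,
    DepthTrack,
    chromosome_coverage,
    depth_from_alignments,
    detect_outlier_chromosomes,
    read_depth_bedgraph,
)
from rdcnv.intervals import GenomicInterval
from rdcnv.simulate import SimulationSpec, simulate_alignments, simulate_depth


def bedgraph(text):
    return io.StringIO(text)


class TestBedgraph:
    def test_constant_interval_gives_constant_track(self):
        track = read_depth_bedgraph(
            bedgraph("c1\t0\t1000\t30\n"), bin_size=50
        )
        np.testing.assert_allclose(track.data["c1"], 30.0)

    def test_split_bin_weighted_mean(self):
        # two adjacent intervals split the second bin in half: (20+40)/2 = 30
        track = read_depth_bedgraph(
            bedgraph("c1\t0\t75\t20\nc1\t75\t150\t40\n"), bin_size=50
        )
        np.testing.assert_allclose(track.data["c1"], [20.0, 30.0, 40.0])

    def test_uncovered_bases_count_as_zero(self):
        track = read_depth_bedgraph(bedgraph("c1\t0\t25\t40\n"), bin_size=50,
                                    chrom_lengths={"c1": 100})
        np.testing.assert_allclose(track.data["c1"], [20.0, 0.0])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="unsorted"):
            read_depth_bedgraph(
                bedgraph("c1\t100\t200\t10\nc1\t0\t50\t10\n"), bin_size=50
            )

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            read_depth_bedgraph(
                bedgraph("c1\t0\t100\t10\nc1\t50\t150\t10\n"), bin_size=50
            )

    def test_last_partial_bin_uses_actual_width(self):
        track = read_depth_bedgraph(
            bedgraph("c1\t0\t70\t10\n"), bin_size=50, chrom_lengths={"c1": 70}
        )
        np.testing.assert_allclose(track.data["c1"], [10.0, 10.0])


class TestAlignments:
    def test_tiling_reads_give_unit_depth(self, tmp_path):
        import pysam

        path = str(tmp_path / "tiled.bam")
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "c1", "LN": 1000}]}
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for i in range(10):
                a = pysam.AlignedSegment()
                a.query_name = f"r{i}"
                a.query_sequence = "A" * 100
                a.reference_id = 0
                a.reference_start = i * 100
                a.cigartuples = [(0, 100)]
                a.mapping_quality = 60
                bam.write(a)
        pysam.index(path)
        track = depth_from_alignments(path, bin_size=50)
        np.testing.assert_allclose(track.data["c1"], 1.0)

    def test_empty_alignments_give_zero_track(self, tmp_path):
        import pysam

        path = str(tmp_path / "empty.bam")
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "c1", "LN": 500}]}
        with pysam.AlignmentFile(path, "wb", header=header):
            pass
        pysam.index(path)
        track = depth_from_alignments(path, bin_size=50)
        np.testing.assert_allclose(track.data["c1"], 0.0)

    def test_filtered_flags_and_deletions(self, tmp_path):
        import pysam

        path = str(tmp_path / "flags.bam")
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "c1", "LN": 300}]}
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            a = pysam.AlignedSegment()  # 40M20D40M covers 100 ref bases
            a.query_name = "del"
            a.query_sequence = "A" * 80
            a.reference_id = 0
            a.reference_start = 0
            a.cigartuples = [(0, 40), (2, 20), (0, 40)]
            bam.write(a)
            b = pysam.AlignedSegment()  # duplicate: ignored
            b.query_name = "dup"
            b.query_sequence = "A" * 100
            b.reference_id = 0
            b.reference_start = 100
            b.cigartuples = [(0, 100)]
            b.flag = 1024
            bam.write(b)
        pysam.index(path)
        track = depth_from_alignments(path, bin_size=100)
        np.testing.assert_allclose(track.data["c1"], [1.0, 0.0, 0.0])

    def test_unsorted_header_rejected(self, tmp_path):
        import pysam

        path = str(tmp_path / "unsorted.bam")
        header = {"HD": {"VN": "1.6", "SO": "unsorted"},
                  "SQ": [{"SN": "c1", "LN": 100}]}
        with pysam.AlignmentFile(path, "wb", header=header):
            pass
        with pytest.raises(ValueError, match="sort"):
            depth_from_alignments(path)

    def test_simulated_coverage_recovered(self, tmp_path):
        spec = SimulationSpec(
            chromosomes=[("c1", 100_000)], coverage=30, seed=11
        )
        path = str(tmp_path / "sim.bam")
        simulate_alignments(spec, path)
        track = depth_from_alignments(path, bin_size=50)
        # mean of per-bin depth within 3 standard errors of 30
        mean = track.data["c1"][:-20].mean()  # clip edge effect at 3' end
        se = 3 * np.sqrt(30 / (100_000 / 100))
        assert abs(mean - 30) < se


class TestChromosomeCoverage:
    def test_constant_depth(self):
        depth = DepthTrack(50, {"c1": 10_000}, {"c1": np.full(200, 30.0)})
        hc = [GenomicInterval("c1", 1_000, 9_000)]
        cov = chromosome_coverage(depth, hc)
        assert cov == {"c1": pytest.approx(30.0)}

    def test_repeat_depth_excluded_by_region_choice(self):
        # unique half at 30x, repeat half at 90x; HC region covers unique only
        arr = np.concatenate([np.full(100, 30.0), np.full(100, 90.0)])
        depth = DepthTrack(50, {"c1": 10_000}, {"c1": arr})
        hc = [GenomicInterval("c1", 0, 5_000)]
        assert chromosome_coverage(depth, hc)["c1"] == pytest.approx(30.0)

    def test_only_longest_n_regions_contribute(self):
        arr = np.full(1000, 10.0)
        arr[:20] = 100.0  # first 1 kb inflated
        depth = DepthTrack(50, {"c1": 50_000}, {"c1": arr})
        # 25 regions; the inflated one is the shortest and must be dropped
        regions = [GenomicInterval("c1", 1_000 + i * 1_900, 1_000 + i * 1_900 + 1_500)
                   for i in range(24)]
        regions.append(GenomicInterval("c1", 0, 900))
        cov = chromosome_coverage(depth, regions, n_regions=20)
        assert cov["c1"] == pytest.approx(10.0)

    def test_chromosome_without_regions_absent(self):
        depth = DepthTrack(50, {"c1": 1_000, "c2": 1_000},
                           {"c1": np.full(20, 5.0), "c2": np.full(20, 5.0)})
        cov = chromosome_coverage(depth, [GenomicInterval("c1", 0, 900)])
        assert "c2" not in cov

    def test_partial_bin_overlap_weighting(self):
        arr = np.array([10.0, 30.0])
        depth = DepthTrack(50, {"c1": 100}, {"c1": arr})
        cov = chromosome_coverage(depth, [GenomicInterval("c1", 25, 75)])
        assert cov["c1"] == pytest.approx(20.0)


class TestOutliers:
    def test_trisomy_like_gain(self):
        per = {f"c{i}": 30.0 for i in range(22)}
        per["c21"] = 45.0
        summary = detect_outlier_chromosomes(per)
        assert summary.outliers == {"c21": "gain"}
        assert summary.overall == pytest.approx(30.0)
        assert summary.aneuploid() == {"c21": "gain"}

    def test_monosomy_like_loss(self):
        per = {f"c{i}": 30.0 for i in range(10)}
        per["c9"] = 15.0
        summary = detect_outlier_chromosomes(per)
        assert summary.outliers == {"c9": "loss"}
        assert summary.aneuploid() == {"c9": "loss"}

    def test_all_equal_no_outliers(self):
        summary = detect_outlier_chromosomes({f"c{i}": 30.0 for i in range(8)})
        assert summary.outliers == {}
        assert summary.overall == pytest.approx(30.0)

    def test_fewer_than_four_chromosomes(self):
        summary = detect_outlier_chromosomes({"a": 10.0, "b": 20.0, "c": 60.0})
        assert summary.outliers == {}
        assert summary.overall == pytest.approx(30.0)

    def test_hand_computed_fences(self):
        # values 1..8 plus 100: Q1=2, Q3=7.. verify against numpy quartiles
        per = {f"c{i}": float(v) for i, v in enumerate([1, 2, 3, 4, 5, 6, 7, 8, 100])}
        q1, q3 = np.percentile(list(per.values()), [25, 75])
        summary = detect_outlier_chromosomes(per)
        expected = {c for c, v in per.items() if v > q3 + 1.5 * (q3 - q1) or v < q1 - 1.5 * (q3 - q1)}
        assert set(summary.outliers) == expected

    def test_moderate_outlier_not_aneuploid(self):
        # a chromosome at 0.75x baseline is excluded from the mean but not
        # treated as a whole-chromosome copy change
        per = {f"c{i}": 30.0 + 0.01 * i for i in range(10)}
        per["cnv"] = 22.5
        summary = detect_outlier_chromosomes(per)
        assert "cnv" in summary.outliers
        assert summary.aneuploid() == {}


class TestEstimatorProperties:
    def test_overall_coverage_unbiased(self):
        # over 100 simulated samples the mean estimate is within 1% of truth
        hc = [GenomicInterval(c, 0, 95_000) for c in ("c1", "c2", "c3", "c4")]
        estimates = []
        for seed in range(100):
            spec = SimulationSpec(
                chromosomes=[(c, 100_000) for c in ("c1", "c2", "c3", "c4")],
                coverage=20,
                seed=seed,
            )
            depth = simulate_depth(spec)
            summary = detect_outlier_chromosomes(chromosome_coverage(depth, hc))
            estimates.append(summary.overall)
        assert abs(np.mean(estimates) - 20) < 0.2
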