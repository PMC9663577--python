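"""Merged binding sites, HOT calling, bin correlation, interval enrichment."""

import numpy as np
import pytest

from polytereg.binding_map import (
    call_hot,
    flat_to_intervals,
    interval_enrichment,
    merge_tfbs,
    tad_boundary_windows,
    tf_binding_correlation,
)
from polytereg.core import GenomicInterval, Peak


def _peak(chrom, start, end, tf):
    return Peak(GenomicInterval(chrom, start, end), (start + end) // 2, 1.0, tf)


class TestMergeTFBS:
    def test_overlapping_peaks_merge_with_distinct_tfs(self):
        sites = merge_tfbs([_peak("1A", 100, 300, "TF1"), _peak("1A", 250, 400, "TF2")])
        assert len(sites) == 1
        assert sites[0].interval.start == 100 and sites[0].interval.end == 400
        assert sites[0].tf_count == 2

    def test_bookended_peaks_stay_separate(self):
        sites = merge_tfbs([_peak("1A", 100, 200, "TF1"), _peak("1A", 200, 300, "TF2")])
        assert len(sites) == 2

    def test_same_tf_counts_once(self):
        sites = merge_tfbs([_peak("1A", 100, 300, "TF1"), _peak("1A", 200, 400, "TF1")])
        assert sites[0].tf_count == 1

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        peaks = [
            _peak("1A", int(s), int(s) + int(w), f"TF{t}")
            for s, w, t in zip(
                rng.integers(0, 5000, 100), rng.integers(10, 200, 100),
                rng.integers(1, 6, 100),
            )
        ]
        sites = merge_tfbs(peaks)
        again = merge_tfbs(
            [Peak(s.interval, s.interval.midpoint, 1.0, "x") for s in sites]
        )
        assert [(s.interval.start, s.interval.end) for s in sites] == [
            (s.interval.start, s.interval.end) for s in again
        ]

    @pytest.mark.parametrize("seed", range(3))
    def test_per_base_coverage_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        size = 10_000
        peaks = [
            _peak("1A", int(s), min(size, int(s) + int(w)), f"TF{t}")
            for s, w, t in zip(
                rng.integers(0, size - 10, 500), rng.integers(10, 120, 500),
                rng.integers(1, 8, 500),
            )
        ]
        sites = merge_tfbs(peaks)
        # brute force: per-base distinct-TF counter
        per_base = [set() for _ in range(size)]
        for p in peaks:
            for i in range(p.interval.start, p.interval.end):
                per_base[i].add(p.tf_id)
        for s in sites:
            expected = set()
            for i in range(s.interval.start, s.interval.end):
                expected |= per_base[i]
            assert s.tf_ids == expected
        # sites are disjoint and jointly cover exactly the covered bases
        covered = np.array([bool(b) for b in per_base])
        site_mask = np.zeros(size, dtype=bool)
        for s in sites:
            assert not site_mask[s.interval.start:s.interval.end].any()
            site_mask[s.interval.start:s.interval.end] = True
        assert (site_mask == covered).all()


class TestCallHot:
    def test_strict_threshold(self):
        peaks = [_peak("1A", 0, 100, f"TF{i}") for i in range(13)]
        peaks += [_peak("1B", 0, 100, f"TF{i}") for i in range(12)]
        sites = merge_tfbs(peaks)
        hot, non_hot = call_hot(sites, threshold=12)
        assert [s.interval.chrom for s in hot] == ["1A"]
        assert [s.interval.chrom for s in non_hot] == ["1B"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            call_hot([], threshold=0)

    def test_planted_pileup_is_only_hot_site(self):
        rng = np.random.default_rng(7)
        peaks = [
            _peak("1A", int(s), int(s) + 50, f"TF{t}")
            for s, t in zip(rng.integers(0, 50_000, 200), rng.integers(1, 6, 200))
        ]
        peaks += [_peak("1A", 90_000, 90_200, f"TF{i}") for i in range(20)]
        sites = merge_tfbs(peaks)
        hot, _ = call_hot(sites)
        assert len(hot) == 1 and hot[0].interval.start == 90_000

    def test_partition_preserves_footprint(self):
        rng = np.random.default_rng(11)
        peaks = [
            _peak("1A", int(s), int(s) + 100, f"TF{t}")
            for s, t in zip(rng.integers(0, 20_000, 300), rng.integers(1, 20, 300))
        ]
        sites = merge_tfbs(peaks)
        hot, non_hot = call_hot(sites)
        total = sum(len(s.interval) for s in sites)
        assert sum(len(s.interval) for s in hot + non_hot) == total


class TestBinCorrelation:
    def test_self_correlation_and_symmetry(self):
        rng = np.random.default_rng(0)
        peaks = {
            tf: [_peak("1A", int(s), int(s) + 100, tf) for s in rng.integers(0, 99_000, 40)]
            for tf in ("TF1", "TF2")
        }
        corr, order = tf_binding_correlation(peaks, {"1A": 100_000})
        assert corr.loc["TF1", "TF1"] == pytest.approx(1.0)
        assert corr.loc["TF1", "TF2"] == pytest.approx(corr.loc["TF2", "TF1"])

    def test_complementary_vectors_anticorrelate(self):
        n_bins = 10
        p1 = [_peak("1A", i * 2000 + 10, i * 2000 + 100, "TF1") for i in range(0, n_bins, 2)]
        p2 = [_peak("1A", i * 2000 + 10, i * 2000 + 100, "TF2") for i in range(1, n_bins, 2)]
        corr, _ = tf_binding_correlation({"TF1": p1, "TF2": p2}, {"1A": 20_000})
        assert corr.loc["TF1", "TF2"] == pytest.approx(-1.0)

    def test_independent_tfs_near_zero(self):
        rng = np.random.default_rng(42)
        size = 20_000_000  # 10^4 bins
        peaks = {
            tf: [_peak("1A", int(s), int(s) + 50, tf)
                 for s in rng.integers(0, size - 50, 3000)]
            for tf in ("TF1", "TF2")
        }
        corr, _ = tf_binding_correlation(peaks, {"1A": size})
        assert abs(corr.loc["TF1", "TF2"]) < 0.05

    def test_constant_vector_reported_missing(self):
        p1 = [_peak("1A", 10, 100, "TF1")]
        corr, _ = tf_binding_correlation(
            {"TF1": p1, "TF2": [], "TF3": p1}, {"1A": 10_000}
        )
        assert np.isnan(corr.loc["TF1", "TF2"])
        assert corr.loc["TF2", "TF2"] == pytest.approx(1.0)


class TestIntervalEnrichment:
    def test_proportional_query_gives_unit_enrichment(self):
        classes = {
            "a": [GenomicInterval("1A", 0, 1000)],
            "b": [GenomicInterval("1A", 1000, 4000)],
        }
        query = [GenomicInterval("1A", 0, 250), GenomicInterval("1A", 1000, 1750)]
        df = interval_enrichment(query, classes, genome_bp=4000)
        assert df.set_index("class")["enrichment"].tolist() == pytest.approx([1.0, 1.0])

    def test_concentrated_query_fold(self):
        classes = {"a": [GenomicInterval("1A", 0, 1000)]}
        query = [GenomicInterval("1A", 100, 300)]
        df = interval_enrichment(query, classes, genome_bp=10_000)
        assert df["enrichment"].iloc[0] == pytest.approx(10.0)

    def test_zero_length_class_rejected(self):
        with pytest.raises(ValueError):
            interval_enrichment(
                [GenomicInterval("1A", 0, 10)], {"a": []}, genome_bp=100
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_concentration_recovered(self, seed):
        rng = np.random.default_rng(seed)
        size = 100_000
        cls = {"hotzone": [GenomicInterval("1A", 0, 10_000)],
               "rest": [GenomicInterval("1A", 10_000, size)]}
        # place 2x the proportional share of query bp into the 10% zone
        query = []
        for _ in range(400):
            if rng.random() < 0.2:
                s = int(rng.integers(0, 10_000 - 50))
            else:
                s = int(rng.integers(10_000, size - 50))
            query.append(GenomicInterval("1A", s, s + 50))
        df = interval_enrichment(query, cls, size).set_index("class")
        assert df.loc["hotzone", "enrichment"] == pytest.approx(2.0, rel=0.25)


class TestTADWindows:
    SIZES = {"1A": 400_000}

    def test_boundary_window_convention(self):
        parts = tad_boundary_windows(
            [GenomicInterval("1A", 100_000, 300_000)], self.SIZES
        )
        assert parts["boundary"]["1A"] == [(90_000, 110_000), (290_000, 310_000)]

    def test_adjacent_tads_share_one_window(self):
        parts = tad_boundary_windows(
            [GenomicInterval("1A", 50_000, 100_000),
             GenomicInterval("1A", 100_000, 180_000)],
            self.SIZES,
        )
        assert (90_000, 110_000) in parts["boundary"]["1A"]
        assert len(parts["boundary"]["1A"]) == 3

    def test_empty_tads_everything_nontad(self):
        parts = tad_boundary_windows([], self.SIZES)
        assert parts["boundary"] == {}
        assert parts["non_tad"]["1A"] == [(0, 400_000)]

    def test_partition_covers_genome_disjointly(self):
        tads = [GenomicInterval("1A", 40_000, 150_000),
                GenomicInterval("1A", 200_000, 360_000)]
        parts = tad_boundary_windows(tads, self.SIZES)
        mask = np.zeros(400_000, dtype=int)
        for flat in parts.values():
            for s, e in flat.get("1A", []):
                mask[s:e] += 1
        assert (mask == 1).all()

    def test_windows_truncated_at_chromosome_edges(self):
        parts = tad_boundary_windows(
            [GenomicInterval("1A", 5_000, 395_000)], self.SIZES
        )
        assert parts["boundary"]["1A"][0] == (0, 15_000)
        assert parts["boundary"]["1A"][-1] == (385_000, 400_000)
        ivs = flat_to_intervals(parts["boundary"])
        assert all(iv.start >= 0 for iv in ivs)
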