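"""Pair-anchored pile-ups: PE-SCAn, APA, promoter-pair groups, stripe decay."""

import numpy as np
import pytest

from hicdelta.aggregate import (loop_apa, pe_scan, promoter_pair_aggregate,
                                stripe_profile, tertile_labels)
from hicdelta.contacts import ContactMatrix, expected_by_distance, observed_over_expected
from hicdelta.grid import FeatureSet, GenomeGrid, Interval, IntervalPair
from hicdelta.simulate import LoopSpec, SimulationConfig, build_intensity, \
    build_truth, sample_counts

from conftest import symmetric


def point(chrom, bin_idx, bs=25_000):
    mid = bin_idx * bs + bs // 2
    return Interval(chrom, mid, mid + 1)


def loop(chrom, bi, bj, bs=25_000):
    return IntervalPair(Interval(chrom, bi * bs, (bi + 1) * bs),
                        Interval(chrom, bj * bs, (bj + 1) * bs))


class TestPeScan:
    def test_uniform_matrix_flat_everywhere(self):
        grid = GenomeGrid(("c",), (200 * 25_000,), 25_000)
        m = ContactMatrix(grid, {"c": np.full((200, 200), 2.0)}, "oe")
        anchors = FeatureSet([point("c", b) for b in (30, 90, 160)])
        res = pe_scan(m, anchors, window_bp=100_000, seed=0)
        assert np.allclose(res.matrix, 2.0)
        assert np.allclose(res.stats["ratio_matrix"], 1.0)
        assert res.stats["raw_center_enrichment"] == pytest.approx(1.0)

    def test_boosted_pair_pixels_recovered_exactly(self):
        grid = GenomeGrid(("c",), (200 * 25_000,), 25_000)
        a = np.ones((200, 200))
        anchors_bins = (40, 100, 170)
        for x in anchors_bins:
            for y in anchors_bins:
                if x < y:
                    a[x, y] = a[y, x] = 3.0
        m = ContactMatrix(grid, {"c": a}, "oe")
        anchors = FeatureSet([point("c", b) for b in anchors_bins])
        res = pe_scan(m, anchors, window_bp=100_000, background_mode="none")
        assert res.n_features == 3
        h = res.matrix.shape[0] // 2
        assert res.matrix[h, h] == pytest.approx(3.0)
        assert res.stats["raw_frame_mean"] == pytest.approx(1.0)
        assert res.stats["raw_center_enrichment"] == pytest.approx(3.0)

    def test_matches_brute_force_window_extraction(self):
        rng = np.random.default_rng(11)
        n = 120
        grid = GenomeGrid(("c",), (n * 25_000,), 25_000)
        a = symmetric(n, rng)
        m = ContactMatrix(grid, {"c": a}, "oe")
        bins = (20, 50, 90)
        anchors = FeatureSet([point("c", b) for b in bins])
        window = 3  # bins
        res = pe_scan(m, anchors, window_bp=window * 25_000,
                      background_mode="none", min_sep_bp=6 * 25_000)
        wins = []
        for x in bins:
            for y in bins:
                if x < y and 6 < y - x <= 400:
                    wins.append(a[x - window : x + window + 1,
                                  y - window : y + window + 1])
        assert np.allclose(res.matrix, np.mean(wins, axis=0), atol=1e-10)

    def test_permuted_background_unenriched_on_structure(self):
        # a matrix whose only structure sits at the true anchors: the
        # permuted background must not see it
        grid = GenomeGrid(("c",), (300 * 25_000,), 25_000)
        a = np.ones((300, 300))
        bins = (50, 120, 200, 260)
        for x in bins:
            for y in bins:
                if x < y:
                    a[x, y] = a[y, x] = 4.0
        m = ContactMatrix(grid, {"c": a}, "oe")
        anchors = FeatureSet([point("c", b) for b in bins])
        cents = []
        for seed in range(30):
            res = pe_scan(m, anchors, window_bp=100_000, seed=seed,
                          background_mode="permute")
            cents.append(res.stats["background_center_enrichment"])
        cents = np.asarray(cents)
        se = cents.std(ddof=1) / np.sqrt(len(cents))
        assert abs(cents.mean() - 1.0) <= max(2 * se, 0.02)

    def test_linearity_in_the_matrix(self):
        rng = np.random.default_rng(5)
        n = 120
        grid = GenomeGrid(("c",), (n * 25_000,), 25_000)
        a, b = symmetric(n, rng), symmetric(n, rng)
        anchors = FeatureSet([point("c", x) for x in (20, 60, 100)])
        kw = dict(window_bp=75_000, background_mode="none")
        ra = pe_scan(ContactMatrix(grid, {"c": a}, "oe"), anchors, **kw)
        rb = pe_scan(ContactMatrix(grid, {"c": b}, "oe"), anchors, **kw)
        rab = pe_scan(ContactMatrix(grid, {"c": a + b}, "oe"), anchors, **kw)
        assert np.allclose(rab.matrix, ra.matrix + rb.matrix, atol=1e-10)


class TestLoopApa:
    def test_center_corner_arithmetic(self):
        grid = GenomeGrid(("c",), (100 * 25_000,), 25_000)
        a = np.full((100, 100), 1.2)
        a[30, 70] = a[70, 30] = 2.4
        m = ContactMatrix(grid, {"c": a}, "oe")
        res = loop_apa(m, FeatureSet([loop("c", 30, 70)]), half_window_bins=5)
        assert res.stats["apa_score"] == pytest.approx(2.0)

    def test_uniform_matrix_scores_one(self):
        grid = GenomeGrid(("c",), (100 * 25_000,), 25_000)
        m = ContactMatrix(grid, {"c": np.ones((100, 100))}, "oe")
        res = loop_apa(m, FeatureSet([loop("c", 20, 60), loop("c", 40, 90)]),
                       half_window_bins=5)
        assert res.stats["apa_score"] == pytest.approx(1.0)

    def test_close_loops_skipped(self):
        grid = GenomeGrid(("c",), (100 * 25_000,), 25_000)
        m = ContactMatrix(grid, {"c": np.ones((100, 100))}, "oe")
        res = loop_apa(m, FeatureSet([loop("c", 20, 25)]), half_window_bins=5)
        assert res.n_features == 0
        assert res.stats["skipped_close"] == 1

    def test_boost_recovery_at_high_depth(self):
        # free-standing loops (no domains) with boost 2.5 on Poisson counts
        cfg = SimulationConfig(seed=0, chrom_lengths={"c": 10_000_000})
        grid = cfg.grid()
        truth_loops = [LoopSpec("c", 40 + 60 * k, 70 + 60 * k, "pol2_only", 2.5)
                       for k in range(5)]
        from test_simulate import bare_truth
        truth = bare_truth(n_bins=400, loops=truth_loops)
        mu = {"c": build_intensity(truth, "c")}
        counts = sample_counts(truth.grid, mu, 10_000_000, seed=1)
        oe = observed_over_expected(counts, expected_by_distance(counts))
        pairs = FeatureSet([loop("c", lp.bin_a, lp.bin_b) for lp in truth_loops])
        res = loop_apa(oe, pairs, half_window_bins=5)
        assert res.stats["apa_score"] == pytest.approx(2.5, rel=0.10)


class TestTertiles:
    def test_nine_split_evenly(self):
        labels = tertile_labels(np.arange(9.0))
        assert [int((labels == k).sum()) for k in range(3)] == [3, 3, 3]

    def test_ten_splits_4_3_3(self):
        labels = tertile_labels(np.arange(10.0))
        assert [int((labels == k).sum()) for k in range(3)] == [4, 3, 3]

    def test_top_slice_holds_highest_scores(self):
        scores = np.array([5.0, 1.0, 9.0, 3.0, 7.0, 2.0])
        labels = tertile_labels(scores)
        assert set(scores[labels == 0]) == {9.0, 7.0}


class TestPromoterPairs:
    def grid_and_promoters(self):
        grid = GenomeGrid(("c",), (400 * 10_000,), 10_000)
        bs = 10_000
        # active promoters at known bins; two of them CTCF-bound
        bins = [40, 80, 150, 230, 300]
        proms = [Interval("c", b * bs + 100, b * bs + 1100,
                          score=float(10 - i)) for i, b in enumerate(bins)]
        ctcf = FeatureSet([Interval("c", bins[0] * bs, bins[0] * bs + 500),
                           Interval("c", bins[1] * bs, bins[1] * bs + 500)])
        return grid, FeatureSet(proms), ctcf, bins

    def test_uniform_matrix_all_groups_unenriched(self):
        grid, proms, ctcf, _ = self.grid_and_promoters()
        m = ContactMatrix(grid, {"c": np.ones((400, 400))}, "oe")
        out = promoter_pair_aggregate(m, proms, ctcf_peaks=ctcf)
        assert out
        for res in out.values():
            assert res.stats["center_enrichment"] == pytest.approx(1.0)

    def test_ctcf_pair_boost_separates_strata(self):
        grid, proms, ctcf, bins = self.grid_and_promoters()
        a = np.ones((400, 400))
        a[bins[0], bins[1]] = a[bins[1], bins[0]] = 5.0  # the CTCF-CTCF pair
        m = ContactMatrix(grid, {"c": a}, "oe")
        out = promoter_pair_aggregate(m, proms, ctcf_peaks=ctcf)
        assert out["intra_tad|ctcf"].stats["center_enrichment"] > \
            out["intra_tad|noctcf"].stats["center_enrichment"] * 2

    def test_distance_classes_partition_pairs(self):
        grid, proms, ctcf, bins = self.grid_and_promoters()
        m = ContactMatrix(grid, {"c": np.ones((400, 400))}, "oe")
        out = promoter_pair_aggregate(m, proms, ctcf_peaks=ctcf)
        seps = [abs(a - b) * 10_000 for i, a in enumerate(bins)
                for b in bins[i + 1 :]]
        n_intra = sum(200_000 <= s < 2_000_000 for s in seps)
        n_long = sum(2_000_000 <= s < 10_000_000 for s in seps)
        assert out["intra_tad"].n_features == n_intra
        assert out["long_range"].n_features == n_long


class TestStripeProfile:
    def test_uniform_matrix_flat_curve(self):
        grid = GenomeGrid(("c",), (200 * 10_000,), 10_000)
        m = ContactMatrix(grid, {"c": np.ones((200, 200))}, "oe")
        targets = FeatureSet([point("c", 100, bs=10_000)])
        curve, agg = stripe_profile(m, targets, max_dist_bp=200_000)
        assert np.allclose(curve, 1.0)
        assert np.allclose(agg.per_feature, 1.0)

    def test_extent_limited_boost(self):
        # boost 2 out to 100 kb; curve ~2 below the extent, ~1 beyond
        grid = GenomeGrid(("c",), (200 * 10_000,), 10_000)
        a = np.ones((200, 200))
        t, ext = 100, 10  # extent 10 bins = 100 kb
        for d in range(1, ext + 1):
            a[t, t - d] = a[t - d, t] = 2.0
            a[t, t + d] = a[t + d, t] = 2.0
        m = ContactMatrix(grid, {"c": a}, "oe")
        curve, _ = stripe_profile(m, FeatureSet([point("c", t, bs=10_000)]),
                                  max_dist_bp=200_000)
        assert np.allclose(curve[:10], 2.0)
        assert np.allclose(curve[10:], 1.0)

    def test_truncated_target_flagged(self):
        grid = GenomeGrid(("c",), (30 * 10_000,), 10_000)
        m = ContactMatrix(grid, {"c": np.ones((30, 30))}, "oe")
        curve, agg = stripe_profile(m, FeatureSet([point("c", 3, bs=10_000)]),
                                    max_dist_bp=200_000)
        assert agg.stats["truncated_targets"] == 1
        assert np.allclose(curve[np.isfinite(curve)], 1.0)
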