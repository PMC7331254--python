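"""Pair filtering, binning, depth matching, ICE balancing, expected/O-E, I/O."""

import numpy as np
import pandas as pd
import pytest

from hicdelta.contacts import (ContactMatrix, bin_pairs, downsample,
                               expected_by_distance, filter_pairs, ice_balance,
                               observed_over_expected, read_matrix, read_pairs,
                               read_weights, write_matrix, write_weights)
from hicdelta.grid import FeatureSet, GenomeGrid, Interval

from conftest import matrix_of, symmetric


def pairs_df(rows):
    return pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2",
                                       "strand1", "strand2"])


@pytest.fixture
def fragments():
    # four 10-kb fragments on chrA
    return FeatureSet([Interval("chrA", i * 10_000, (i + 1) * 10_000)
                       for i in range(25)])


class TestFilterPairs:
    def test_duplicate_and_same_fragment_removed(self, fragments):
        rows = [
            ("chrA", 1_000, "chrA", 55_000, "+", "-"),   # keep
            ("chrA", 21_000, "chrA", 95_000, "+", "+"),  # keep
            ("chrA", 40_500, "chrA", 80_200, "-", "-"),  # keep
            ("chrA", 1_000, "chrA", 55_000, "+", "-"),   # exact duplicate of #1
            ("chrA", 12_000, "chrA", 13_000, "+", "-"),  # same fragment
        ]
        out, stats = filter_pairs(pairs_df(rows), fragments)
        assert len(out) == 3
        assert stats.duplicate == 1
        assert stats.same_fragment == 1

    def test_clean_input_passes_through(self, fragments):
        rows = [("chrA", 1_000, "chrA", 55_000, "+", "-"),
                ("chrA", 21_000, "chrA", 95_000, "+", "+")]
        out, stats = filter_pairs(pairs_df(rows), fragments)
        assert len(out) == 2
        assert stats.duplicate == stats.same_fragment == 0

    def test_empty_input(self, fragments):
        out, stats = filter_pairs(pairs_df([]), fragments)
        assert len(out) == 0
        assert stats.retained == 0

    def test_missing_fragments_is_configuration_error(self):
        with pytest.raises(ValueError, match="fragment"):
            filter_pairs(pairs_df([("chrA", 0, "chrA", 100, "+", "-")]))


class TestBinPairs:
    def test_two_pairs_same_cell(self, small_grid):
        df = pairs_df([("chrA", 1_000, "chrA", 30_000, "+", "-"),
                       ("chrA", 2_000, "chrA", 26_000, "+", "-")])
        m = bin_pairs(df, small_grid)
        assert m.value("chrA", 0, 1) == 2

    def test_diagonal_pair(self, small_grid):
        df = pairs_df([("chrA", 100_000, "chrA", 101_000, "+", "-")])
        m = bin_pairs(df, small_grid)
        assert m.value("chrA", 4, 4) == 1

    def test_conservation(self, small_grid):
        rng = np.random.default_rng(0)
        rows = [("chrA", int(rng.integers(0, 250_000)),
                 "chrA", int(rng.integers(0, 250_000)), "+", "-")
                for _ in range(10)]
        m = bin_pairs(pairs_df(rows), small_grid)
        assert m.total_count == 10

    def test_trans_kept_as_statistic(self, small_grid):
        df = pairs_df([("chrA", 0, "chrB", 0, "+", "-"),
                       ("chrA", 0, "chrA", 30_000, "+", "-")])
        m = bin_pairs(df, small_grid)
        assert m.trans_count == 1
        assert m.total_count == 1


class TestDownsample:
    def test_full_target_is_identity(self, small_grid):
        rng = np.random.default_rng(1)
        m = matrix_of(small_grid,
                      {c: symmetric(small_grid.n_bins(c), rng, integer=True)
                       for c in small_grid.chrom_names}, kind="count")
        out = downsample(m, int(m.total_count), seed=0)
        for c in small_grid.chrom_names:
            assert np.array_equal(out.dense(c), m.dense(c))

    def test_zero_target(self, small_grid):
        m = matrix_of(small_grid, {c: np.ones((small_grid.n_bins(c),) * 2)
                                   for c in small_grid.chrom_names}, kind="count")
        out = downsample(m, 0, seed=0)
        assert out.total_count == 0

    def test_target_exceeding_total_raises(self, small_grid):
        m = matrix_of(small_grid, {c: np.zeros((small_grid.n_bins(c),) * 2)
                                   for c in small_grid.chrom_names}, kind="count")
        with pytest.raises(ValueError):
            downsample(m, 10, seed=0)

    def test_total_conserved_exactly_and_reproducible(self, small_grid):
        rng = np.random.default_rng(2)
        m = matrix_of(small_grid,
                      {c: symmetric(small_grid.n_bins(c), rng, integer=True)
                       for c in small_grid.chrom_names}, kind="count")
        out1 = downsample(m, 37, seed=5)
        out2 = downsample(m, 37, seed=5)
        assert out1.total_count == 37
        for c in small_grid.chrom_names:
            assert np.array_equal(out1.dense(c), out2.dense(c))

    def test_unbiased_cell_mean(self):
        # one cell holds 100 of 1000 contacts; sampling half of them over
        # 200 seeds must average ~50 (hypergeometric mean, s.e. ~0.34)
        grid = GenomeGrid(("c",), (125_000,), 25_000)
        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 100
        a[2, 3] = a[3, 2] = 450
        a[0, 4] = a[4, 0] = 450
        m = ContactMatrix(grid, {"c": a}, "count")
        got = np.mean([downsample(m, 500, seed=s).value("c", 0, 1)
                       for s in range(200)])
        assert abs(got - 50.0) < 2.0


class TestIceBalance:
    def test_uniform_off_diagonal_stays_uniform(self):
        grid = GenomeGrid(("c",), (250_000,), 25_000)
        a = np.full((10, 10), 4.0)
        np.fill_diagonal(a, 0.0)
        bal, w = ice_balance(ContactMatrix(grid, {"c": a}, "count"))
        wv = w["c"]
        assert np.allclose(wv, wv[0])
        off = bal.dense("c")[~np.eye(10, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_marginals_equalized(self):
        grid = GenomeGrid(("c",), (75_000,), 25_000)
        a = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]])
        a[0, :] *= 2  # bin 0 twice as visible
        a[:, 0] *= 2
        a[0, 0] = 0
        a = (a + a.T) / 2
        bal, _ = ice_balance(ContactMatrix(grid, {"c": np.round(a)}, "count"),
                             tol=1e-8)
        marg = np.nansum(bal.dense("c"), axis=1)
        assert np.std(marg) / np.mean(marg) < 1e-6

    def test_zero_bin_masked(self):
        grid = GenomeGrid(("c",), (100_000,), 25_000)
        a = np.full((4, 4), 3.0)
        a[2, :] = 0.0
        a[:, 2] = 0.0
        bal, w = ice_balance(ContactMatrix(grid, {"c": a}, "count"))
        assert np.isnan(w["c"][2])
        assert np.isnan(bal.dense("c")[2]).all()
        assert not bal.bin_mask["c"][2]

    def test_invariant_to_bin_visibility_scaling(self):
        # multiplying one bin's row+column by a constant changes the balanced
        # matrix only by a global scale
        rng = np.random.default_rng(3)
        grid = GenomeGrid(("c",), (300_000,), 25_000)
        a = symmetric(12, rng, integer=True) + 1
        b = a.copy()
        b[4, :] *= 3
        b[:, 4] *= 3
        b[4, 4] = a[4, 4] * 9  # visibility scaling hits the diagonal twice
        bal_a, _ = ice_balance(ContactMatrix(grid, {"c": a}, "count"), tol=1e-10)
        bal_b, _ = ice_balance(ContactMatrix(grid, {"c": b}, "count"), tol=1e-10)
        ratio = bal_b.dense("c") / bal_a.dense("c")
        finite = np.isfinite(ratio) & (bal_a.dense("c") > 0)
        assert np.allclose(ratio[finite], ratio[finite].flat[0], rtol=1e-4)

    def test_all_zero_matrix_raises(self, small_grid):
        m = matrix_of(small_grid, {c: np.zeros((small_grid.n_bins(c),) * 2)
                                   for c in small_grid.chrom_names}, kind="count")
        with pytest.raises(ValueError):
            ice_balance(m)


class TestExpectedAndOE:
    def test_constant_by_distance_recovered_exactly(self):
        grid = GenomeGrid(("c",), (250_000,), 25_000)
        n = 10
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        a = (10.0 - d).astype(float)
        prof = expected_by_distance(ContactMatrix(grid, {"c": a}, "balanced"),
                                    min_diag=0)
        for k in range(n):
            assert prof.expected("c", k) == 10.0 - k

    def test_manual_mean_at_distance_one(self):
        grid = GenomeGrid(("c",), (100_000,), 25_000)
        a = np.zeros((4, 4))
        for (i, j), v in zip(((0, 1), (1, 2), (2, 3)), (2.0, 4.0, 6.0)):
            a[i, j] = a[j, i] = v
        prof = expected_by_distance(ContactMatrix(grid, {"c": a}, "balanced"),
                                    min_diag=0)
        assert prof.expected("c", 1) == 4.0

    def test_no_valid_pairs_gives_nan_not_zero(self):
        grid = GenomeGrid(("c",), (100_000,), 25_000)
        a = np.full((4, 4), np.nan)
        a[0, 1] = a[1, 0] = 2.0
        m = ContactMatrix(grid, {"c": a}, "balanced")
        prof = expected_by_distance(m, min_diag=0)
        assert np.isnan(prof.expected("c", 3))

    def test_oe_mean_one_per_distance(self):
        rng = np.random.default_rng(4)
        grid = GenomeGrid(("c",), (750_000,), 25_000)
        a = symmetric(30, rng) + 0.5
        m = ContactMatrix(grid, {"c": a}, "balanced")
        oe = observed_over_expected(m, expected_by_distance(m, min_diag=0))
        od = oe.dense("c")
        for d in range(30):
            vals = np.diagonal(od, offset=d)
            assert abs(np.nanmean(vals) - 1.0) < 1e-9

    def test_cell_over_expected(self):
        grid = GenomeGrid(("c",), (100_000,), 25_000)
        a = np.zeros((4, 4))
        a[0, 2] = a[2, 0] = 6.0
        a[1, 3] = a[3, 1] = 2.0  # e(2) = (6 + 2) / 2 = 4 -> but manual check below
        m = ContactMatrix(grid, {"c": a}, "count")
        prof = expected_by_distance(m, min_diag=0)
        oe = observed_over_expected(m, prof)
        assert oe.value("c", 0, 2) == 6.0 / prof.expected("c", 2)

    def test_uniform_matrix_gives_all_ones(self):
        grid = GenomeGrid(("c",), (250_000,), 25_000)
        m = ContactMatrix(grid, {"c": np.full((10, 10), 5.0)}, "balanced")
        oe = observed_over_expected(m, expected_by_distance(m, min_diag=0))
        assert np.allclose(oe.dense("c"), 1.0)


class TestMatrixIO:
    def test_roundtrip_exact(self, tmp_path, small_grid):
        rng = np.random.default_rng(5)
        m = matrix_of(small_grid,
                      {c: symmetric(small_grid.n_bins(c), rng, integer=True)
                       for c in small_grid.chrom_names}, kind="count")
        write_matrix(m, tmp_path / "m.matrix", tmp_path / "m_abs.bed")
        back = read_matrix(tmp_path / "m.matrix", tmp_path / "m_abs.bed", small_grid)
        for c in small_grid.chrom_names:
            assert np.array_equal(back.dense(c), m.dense(c))

    def test_lower_triangle_input_canonicalized(self, tmp_path, small_grid):
        write_matrix(matrix_of(small_grid,
                               {c: np.zeros((small_grid.n_bins(c),) * 2)
                                for c in small_grid.chrom_names}, kind="count"),
                     tmp_path / "m.matrix", tmp_path / "m_abs.bed")
        (tmp_path / "m.matrix").write_text("3\t1\t7\n")  # (j, i) ordering
        back = read_matrix(tmp_path / "m.matrix", tmp_path / "m_abs.bed", small_grid)
        assert back.value("chrA", 0, 2) == 7

    def test_mismatched_bin_width_raises(self, tmp_path, small_grid):
        m = matrix_of(small_grid, {c: np.zeros((small_grid.n_bins(c),) * 2)
                                   for c in small_grid.chrom_names}, kind="count")
        write_matrix(m, tmp_path / "m.matrix", tmp_path / "m_abs.bed")
        other = GenomeGrid(("chrA", "chrB"), (250_000, 150_000), 50_000)
        with pytest.raises(ValueError):
            read_matrix(tmp_path / "m.matrix", tmp_path / "m_abs.bed", other)

    def test_bin_id_outside_grid_raises(self, tmp_path, small_grid):
        m = matrix_of(small_grid, {c: np.zeros((small_grid.n_bins(c),) * 2)
                                   for c in small_grid.chrom_names}, kind="count")
        write_matrix(m, tmp_path / "m.matrix", tmp_path / "m_abs.bed")
        (tmp_path / "m.matrix").write_text("1\t99\t3\n")
        with pytest.raises(ValueError):
            read_matrix(tmp_path / "m.matrix", tmp_path / "m_abs.bed", small_grid)

    def test_weights_sidecar_roundtrip(self, tmp_path, small_grid):
        w = {c: np.arange(small_grid.n_bins(c), dtype=float) + 0.5
             for c in small_grid.chrom_names}
        w["chrA"][3] = np.nan
        write_weights(w, small_grid, tmp_path / "w.tsv")
        back = read_weights(tmp_path / "w.tsv", small_grid)
        for c in small_grid.chrom_names:
            assert np.array_equal(back[c], w[c], equal_nan=True)


class TestPairsReader:
    def test_pairs_file(self, tmp_path):
        p = tmp_path / "x.pairs"
        p.write_text("## pairs format v1.0\n"
                     "#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n"
                     "r1\tchrA\t5000\tchrA\t1000\t+\t-\n")
        df = read_pairs(p)
        assert len(df) == 1
        assert df.loc[0, "pos1"] == 1000  # canonical order
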