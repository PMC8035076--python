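"""Contact-matrix filtering, balancing, expected/O-E, P(s) and virtual 4C."""

import numpy as np
import pytest
from scipy import sparse

from conftest import random_matrix, toeplitz_matrix
from dvchrom.genome import BinTable, ChromSizes, GenomicInterval
from dvchrom.matrix import (
    BalancingError,
    ContactMatrix,
    coarsen,
    contact_decay,
    expected_profile,
    filter_low_coverage,
    ice_balance,
    kr_balance,
    observed_expected,
    virtual_4c,
)
from dvchrom.matrixio import load_coo, load_hdf5, save_coo, save_hdf5


def _diag_matrix(marginals, bin_size=1000):
    n = len(marginals)
    cs = ChromSizes({"c": n * bin_size})
    return ContactMatrix.from_dense(
        np.diag(np.asarray(marginals, float)), BinTable(cs, bin_size)
    )


class TestFilterLowCoverage:
    def test_ten_percent_of_median_rule(self):
        m = filter_low_coverage(_diag_matrix([100, 90, 80, 5]))
        assert list(m.valid) == [True, True, True, False]

    def test_equal_marginals_keep_everything(self):
        m = filter_low_coverage(_diag_matrix([7, 7, 7, 7]))
        assert m.valid.all()

    def test_idempotent(self):
        m = filter_low_coverage(_diag_matrix([100, 90, 80, 5]))
        assert list(filter_low_coverage(m).valid) == list(m.valid)

    def test_matches_brute_force_on_lognormal_marginals(self, rng):
        marg = rng.lognormal(3, 1.5, size=200)
        m = filter_low_coverage(_diag_matrix(marg))
        threshold = 0.10 * np.median(marg[marg > 0])
        assert (m.valid == (marg >= threshold)).all()

    def test_all_masked_is_an_error(self):
        with pytest.raises(BalancingError):
            filter_low_coverage(_diag_matrix([0.0, 0.0]))


class TestBalancing:
    def _normalized(self, m):
        return m.normalized_dense("c" if "c" in m.bins.chrom_sizes else None)

    def test_kr_uniform_2x2(self):
        m = ContactMatrix.from_dense(
            np.ones((2, 2)), BinTable(ChromSizes({"c": 2000}), 1000)
        )
        out = kr_balance(m).normalized_dense()
        np.testing.assert_allclose(out, 0.5, atol=1e-9)

    def test_kr_2x2_closed_form(self):
        # symmetric [[2,1],[1,2]]: b^2 * 3 = 1 per row -> b = 1/sqrt(3)
        m = ContactMatrix.from_dense(
            np.array([[2.0, 1.0], [1.0, 2.0]]),
            BinTable(ChromSizes({"c": 2000}), 1000),
        )
        out = kr_balance(m)
        np.testing.assert_allclose(out.biases, 1 / np.sqrt(3), atol=1e-9)
        np.testing.assert_allclose(
            out.normalized_dense(),
            np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]]),
            atol=1e-9,
        )

    def test_ice_uniform_2x2(self):
        m = ContactMatrix.from_dense(
            np.ones((2, 2)), BinTable(ChromSizes({"c": 2000}), 1000)
        )
        np.testing.assert_allclose(
            ice_balance(m).normalized_dense(), 0.5, atol=1e-7
        )

    def test_kr_rowsums_and_sinkhorn_oracle(self, rng):
        a = rng.uniform(1, 10, size=(50, 50))
        a = (a + a.T) / 2
        m = ContactMatrix.from_dense(a, BinTable(ChromSizes({"c": 50_000}), 1000))
        out = kr_balance(m)
        rows = out.normalized_dense().sum(axis=1)
        assert np.abs(rows - 1).max() < 1e-8
        # independent Sinkhorn oracle
        b = np.ones(50)
        for _ in range(10000):
            s = b * (a @ b)
            if np.abs(s - 1).max() < 1e-12:
                break
            b /= np.sqrt(s)
        np.testing.assert_allclose(
            out.normalized_dense(), a * np.outer(b, b), atol=1e-6
        )

    def test_kr_and_ice_agree_elementwise(self, rng):
        a = rng.uniform(1, 10, size=(40, 40))
        a = (a + a.T) / 2
        m = ContactMatrix.from_dense(a, BinTable(ChromSizes({"c": 40_000}), 1000))
        dk = kr_balance(m).normalized_dense()
        di = ice_balance(m).normalized_dense()
        assert np.abs(dk - di).max() < 1e-6

    def test_unbalanceable_zero_row_errors(self):
        a = np.array([[1.0, 0.0], [0.0, 0.0]])
        m = ContactMatrix.from_dense(a, BinTable(ChromSizes({"c": 2000}), 1000))
        with pytest.raises(BalancingError):
            ice_balance(m)
        with pytest.raises(BalancingError):
            kr_balance(m)

    def test_sparse_storage_order_is_irrelevant(self, rng):
        a = rng.uniform(1, 5, size=(20, 20))
        a = np.triu((a + a.T) / 2)
        bins = BinTable(ChromSizes({"c": 20_000}), 1000)
        coo = sparse.coo_matrix(a)
        perm = rng.permutation(coo.nnz)
        shuffled = sparse.coo_matrix(
            (coo.data[perm], (coo.row[perm], coo.col[perm])), shape=coo.shape
        ).tocsr()
        m1 = ContactMatrix(bins, sparse.csr_matrix(a), np.ones(20, bool))
        m2 = ContactMatrix(bins, shuffled, np.ones(20, bool))
        np.testing.assert_allclose(
            kr_balance(m1).normalized_dense(), kr_balance(m2).normalized_dense()
        )


class TestExpectedAndOE:
    def test_toeplitz_expected_recovers_diagonal_values(self):
        vals = [2.0 ** (-d) for d in range(10)]
        m = toeplitz_matrix(10, 1000, vals)
        exp = expected_profile(m)
        np.testing.assert_allclose(exp.cis["chrT"], vals, atol=1e-12)

    def test_oe_of_toeplitz_is_all_ones(self):
        m = toeplitz_matrix(8, 1000, [4, 2, 1, 0.5, 0.25, 0.1, 0.05, 0.02])
        oe = observed_expected(m)["chrT"]
        np.testing.assert_allclose(oe, 1.0, atol=1e-12)

    def test_per_distance_mean_of_oe_is_one(self, rng):
        m = random_matrix(100, 1000, rng)
        oe = observed_expected(m)["chrR"]
        for d in range(100):
            v = np.diagonal(oe, offset=d)
            v = v[np.isfinite(v)]
            if v.size:
                assert abs(v.mean() - 1) < 1e-12

    def test_expected_matches_brute_force_diagonals(self, rng):
        m = random_matrix(100, 1000, rng)
        exp = expected_profile(m).cis["chrR"]
        dense = m.normalized_dense()
        for d in range(100):
            v = np.diagonal(dense, offset=d)
            np.testing.assert_allclose(exp[d], v.mean(), rtol=1e-12)

    def test_masked_bin_row_is_missing(self, rng):
        m = random_matrix(20, 1000, rng)
        m.valid[3] = False
        oe = observed_expected(m)["chrR"]
        assert np.isnan(oe[3, :]).all() and np.isnan(oe[:, 3]).all()


class TestContactDecay:
    def test_power_law_derivative(self):
        n, alpha, s0 = 400, 1.0, 1000
        d = np.arange(n) * 1000
        m = toeplitz_matrix(n, 1000, (d + s0) ** (-alpha))
        curve = contact_decay(m, log_bin_factor=1.15)
        mid = (curve.distances > 20_000) & (curve.distances < 200_000)
        assert np.abs(curve.derivative[mid] + alpha).max() < 0.1

    def test_fine_binning_reproduces_diagonal_means(self):
        vals = np.zeros(50)
        vals[10] = 3.0
        vals[25] = 1.0
        m = toeplitz_matrix(50, 1000, vals)
        # log_bin_factor close to 1 puts every distance in its own bin
        curve = contact_decay(m, log_bin_factor=1.01, total_sum_normalize=False)
        np.testing.assert_allclose(curve.ps, vals[1:], atol=1e-12)

    def test_total_sum_normalization_is_depth_invariant(self):
        vals = [(d + 1.0) ** -1 for d in range(100)]
        m1 = toeplitz_matrix(100, 1000, vals)
        m2 = toeplitz_matrix(100, 1000, [5 * v for v in vals])
        c1 = contact_decay(m1)
        c2 = contact_decay(m2)
        np.testing.assert_allclose(c1.ps, c2.ps, rtol=1e-12)


class TestVirtual4C:
    def test_single_bin_anchor_equals_matrix_row(self, rng):
        m = random_matrix(30, 1000, rng)
        track = virtual_4c(m, GenomicInterval("chrR", 5000, 6000))
        np.testing.assert_allclose(track, m.normalized_dense()[5, :])

    def test_two_bin_anchor_is_row_mean(self, rng):
        m = random_matrix(30, 1000, rng)
        track = virtual_4c(m, GenomicInterval("chrR", 5000, 7000))
        dense = m.normalized_dense()
        np.testing.assert_allclose(track, dense[[5, 6], :].mean(axis=0))

    def test_masked_anchor_errors(self, rng):
        m = random_matrix(10, 1000, rng)
        m.valid[2] = False
        with pytest.raises(ValueError):
            virtual_4c(m, GenomicInterval("chrR", 2000, 3000))


def test_coarsen_preserves_total_counts(rng):
    a = rng.poisson(3.0, size=(30, 30)).astype(float)
    a = np.triu(a) + np.triu(a, 1).T
    m = ContactMatrix.from_dense(a, BinTable(ChromSizes({"c": 30_000}), 1000))
    mc = coarsen(m, 3)
    assert mc.bins.bin_size == 3000
    assert mc.counts.sum() == m.counts.sum()
    # spot-check one coarse pixel against the fine-block sum (upper triangle)
    sym_fine = m.symmetric().toarray()
    sym_coarse = mc.symmetric().toarray()
    assert sym_coarse[0, 1] == sym_fine[0:3, 3:6].sum()


class TestMatrixIO:
    def _example(self, rng):
        a = rng.poisson(2.0, size=(12, 12)).astype(float)
        a = np.triu(a) + np.triu(a, 1).T
        bins = BinTable(ChromSizes({"a": 8000, "b": 4000}), 1000)
        m = ContactMatrix.from_dense(a, bins)
        m.valid[5] = False
        m.biases = rng.uniform(0.5, 2.0, 12)
        return m

    def test_coo_round_trip(self, tmp_path, rng):
        m = self._example(rng)
        save_coo(m, tmp_path / "m")
        back = load_coo(tmp_path / "m")
        assert back.bins == m.bins
        np.testing.assert_allclose(
            back.symmetric().toarray(), m.symmetric().toarray()
        )
        assert (back.valid == m.valid).all()
        np.testing.assert_allclose(back.biases, m.biases)

    def test_hdf5_round_trip(self, tmp_path, rng):
        m = self._example(rng)
        save_hdf5(m, tmp_path / "m.cool")
        back = load_hdf5(tmp_path / "m.cool")
        assert back.bins == m.bins
        np.testing.assert_allclose(
            back.symmetric().toarray(), m.symmetric().toarray()
        )
        np.testing.assert_allclose(back.biases, m.biases)
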