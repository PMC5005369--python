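"""Order estimation, whitening, Infomax and Z-map behavior."""

import numpy as np
import pytest
from scipy import stats as sps

from sbmorph import (
    decompose,
    estimate_order_mdl,
    infomax_ica,
    match_components,
    whiten,
    zscale_and_threshold,
)
from sbmorph.decompose import _fix_signs_and_scale
from sbmorph.evaluate import amari_index
from sbmorph.preprocess import Mask
from tests.conftest import study_matrix


def mdl_oracle(X):
    """Brute-force MDL curve, coded independently of the implementation."""
    Xc = X - X.mean(axis=0)
    V = Xc.shape[1]
    ev = np.linalg.eigvalsh(Xc @ Xc.T / V)[::-1]
    ev = ev[ev > ev[0] * 1e-10]
    p = len(ev)
    best, best_val = None, np.inf
    for k in range(1, p):
        tail = ev[k:]
        gm = np.exp(np.mean(np.log(tail)))
        am = np.mean(tail)
        val = -V * (p - k) * np.log(gm / am) + 0.5 * k * (2 * p - k + 1) * np.log(V)
        if val < best_val:
            best, best_val = k, val
    return best


def toy_whiten(X):
    """Classic row-oriented whitening for small ICA toys (no row centering
    across a subject dimension; rows are mixtures, columns samples)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    d, E = np.linalg.eigh(Xc @ Xc.T / Xc.shape[1])
    K = (E / np.sqrt(d)).T
    return K @ Xc, K


class TestMDL:
    def test_planted_rank_three_recovered(self, rng):
        L = rng.standard_normal((80, 3)) * np.array([9.0, 7.0, 5.0])
        M = rng.standard_normal((3, 4000))
        X = L @ M + rng.standard_normal((80, 4000))
        assert estimate_order_mdl(X) == 3
        assert estimate_order_mdl(X) == mdl_oracle(X)

    def test_pure_noise_returns_minimum_order(self, rng):
        X = rng.standard_normal((40, 8000))
        assert estimate_order_mdl(X) == 1

    def test_matches_independent_curve_on_random_spectra(self, rng):
        for _ in range(5):
            k_true = int(rng.integers(2, 7))
            L = rng.standard_normal((60, k_true)) * rng.uniform(4, 10, k_true)
            X = L @ rng.standard_normal((k_true, 3000)) + rng.standard_normal(
                (60, 3000)
            )
            assert estimate_order_mdl(X) == mdl_oracle(X)

    def test_degenerate_spectrum_returns_one_with_warning(self):
        v = np.arange(10.0)
        X = np.vstack([v, -v])  # rank 1 after per-voxel centering
        with pytest.warns(UserWarning, match="degenerate"):
            assert estimate_order_mdl(X) == 1


class TestWhitening:
    def test_whitened_covariance_is_identity(self, rng):
        X = rng.standard_normal((15, 400))
        wh = whiten(X, 8)
        cov = wh.Y @ wh.Y.T / wh.Y.shape[1]
        np.testing.assert_allclose(cov, np.eye(8), atol=1e-8)

    def test_dewhitening_gives_rank_k_pca_reconstruction(self, rng):
        X = rng.standard_normal((12, 300))
        k = 5
        wh = whiten(X, k)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        pca_k = U[:, :k] @ np.diag(s[:k]) @ Vt[:k]
        np.testing.assert_allclose(wh.dewhitener @ wh.Y, pca_k, atol=1e-8)

    def test_k_exceeding_rank_rejected(self, rng):
        L = rng.standard_normal((10, 2))
        X = L @ rng.standard_normal((2, 100))
        with pytest.raises(ValueError, match="rank"):
            whiten(X, 5)

    def test_one_dimensional_case_unit_mean_square(self, rng):
        X = np.outer(rng.standard_normal(6), rng.standard_normal(50))
        wh = whiten(X, 1)
        # whitened coordinate has unit second moment across voxels and is
        # proportional to the single underlying voxel pattern
        assert np.mean(wh.Y**2) == pytest.approx(1.0, abs=1e-10)
        Xc = X - X.mean(axis=0)
        r = np.corrcoef(wh.Y[0], Xc[0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalues_descending_nonnegative(self, rng):
        wh = whiten(rng.standard_normal((10, 200)), 3)
        assert np.all(np.diff(wh.eigenvalues) <= 1e-12)
        assert np.all(wh.eigenvalues >= -1e-12)


class TestInfomax:
    def test_separates_laplace_toy_mixture(self):
        rng = np.random.default_rng(7)
        S = rng.laplace(size=(2, 20000))
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        Y, K = toy_whiten(A @ S)
        W, info = infomax_ica(Y, seed=0)
        assert amari_index(W @ K @ A) < 0.05

    def test_independent_whitened_input_gives_signed_permutation(self):
        rng = np.random.default_rng(8)
        S = rng.laplace(size=(3, 20000))
        Y = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)
        W, _ = infomax_ica(Y, seed=1)
        Wn = np.abs(W) / np.abs(W).max(axis=1, keepdims=True)
        for row in Wn:
            assert np.sort(row)[-2] < 0.1  # one dominant entry per row

    def test_same_seed_bit_identical(self, rng):
        Y, _ = toy_whiten(rng.laplace(size=(3, 5000)))
        W1, _ = infomax_ica(Y, seed=3)
        W2, _ = infomax_ica(Y, seed=3)
        assert np.array_equal(W1, W2)

    def test_blowup_raises_after_bounded_retries(self, rng):
        Y, _ = toy_whiten(rng.laplace(size=(2, 2000)))
        with pytest.raises(RuntimeError, match="diverged"):
            infomax_ica(Y, seed=0, learning_rate=1e6, max_restarts=1)


class TestDecompose:
    def test_reconstruction_matches_rank_k_pca(self, small_matrix):
        res = decompose(small_matrix, 3, seed=0)
        assert res.relative_reconstruction_error(small_matrix) <= 1e-6

    def test_recovers_planted_sources(self, small_study, small_matrix):
        res = decompose(small_matrix, 3, seed=0)
        _, r = match_components(
            small_study.sources.maps, res.S, small_matrix.mask
        )
        assert np.all(r >= 0.9)

    def test_group_effect_transfers_to_matched_loadings(
        self, paper_study, paper_matrix
    ):
        res = decompose(paper_matrix, 8, seed=0)
        assign, r = match_components(
            paper_study.sources.maps, res.S, paper_matrix.mask
        )
        j = assign[paper_study.design.affected_component]
        lam = res.A[:, j]
        nc = paper_study.design.n_control
        x, y = lam[:nc], lam[nc:]
        pooled = np.sqrt(
            ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
            / (x.size + y.size - 2)
        )
        d = abs(y.mean() - x.mean()) / pooled
        assert abs(d - paper_study.design.effect_size_d) <= 0.3

    def test_sign_convention_positive_skew_and_unit_variance(self, small_matrix):
        res = decompose(small_matrix, 3, seed=1)
        for j in range(3):
            assert sps.skew(res.S[j]) > 0
            assert res.S[j].std() == pytest.approx(1.0, abs=1e-10)

    def test_sign_flip_is_absorbed_by_convention(self, small_matrix):
        res = decompose(small_matrix, 3, seed=2)
        A = res.A.copy()
        S = res.S.copy()
        A[:, 1] *= -1
        S[1] *= -1
        np.testing.assert_allclose(A @ S, res.A @ res.S, atol=1e-10)
        A2, S2 = _fix_signs_and_scale(A, S)
        np.testing.assert_allclose(A2, res.A, atol=1e-10)
        np.testing.assert_allclose(S2, res.S, atol=1e-10)


class TestZMap:
    def _mask(self, shape=(40, 40, 40)):
        return Mask(np.ones(shape, bool), np.eye(4))

    def test_standard_normal_tail_fraction(self):
        mask = self._mask()
        z = np.random.default_rng(5).standard_normal(mask.n_voxels)
        zm = zscale_and_threshold(z, mask, 2.5)
        expected = 2 * sps.norm.sf(2.5)
        tol = 4 * np.sqrt(expected * (1 - expected) / mask.n_voxels)
        assert abs(zm.surviving.mean() - expected) < tol

    def test_subthreshold_component_gives_empty_map(self):
        mask = self._mask((10, 10, 10))
        s = np.tile([-1.0, 1.0], mask.n_voxels // 2)  # max |Z| == 1 < 2.5
        zm = zscale_and_threshold(s, mask, 2.5)
        assert not zm.surviving.any()

    def test_zero_variance_row_rejected(self):
        mask = self._mask((6, 6, 6))
        with pytest.raises(ValueError, match="zero-variance"):
            zscale_and_threshold(np.ones(mask.n_voxels), mask)

    def test_in_mask_mean_zero_unit_variance(self, rng):
        keep = rng.random((12, 12, 12)) > 0.3
        mask = Mask(keep, np.eye(4))
        zm = zscale_and_threshold(rng.random(mask.n_voxels), mask, 2.5)
        vals = zm.values[keep]
        assert vals.mean() == pytest.approx(0.0, abs=1e-8)
        assert vals.var() == pytest.approx(1.0, abs=1e-8)
        assert np.all(zm.values[~keep] == 0)

    def test_one_sided_threshold_keeps_positive_only(self, rng):
        mask = self._mask((20, 20, 20))
        z = rng.standard_normal(mask.n_voxels)
        zm = zscale_and_threshold(z, mask, 2.5, two_sided=False)
        assert np.all(zm.values[zm.surviving] > 2.5)
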