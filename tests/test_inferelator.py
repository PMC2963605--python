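"""Constrained lasso stage: path correctness, CV, explanatory power."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from grninfer.datamodel import ConfidenceMatrix
from grninfer.inferelator import (
    GeneFit,
    fit_gene_model,
    inferelator_confidences,
    lasso_at_fraction,
    select_candidates,
)


def _center_cols(X):
    return X - X.mean(axis=0)


def _oracle_constrained_lasso(U, y, s, tol=1e-10):
    """Independent oracle: coordinate-descent lasso in the penalty (lambda)
    form, mapped onto the constraint form ||b||_1 <= s*||b_OLS||_1 by
    bisection on the achieved L1 norm."""
    beta_ols, *_ = np.linalg.lstsq(U, y, rcond=None)
    target = s * np.abs(beta_ols).sum()
    if target <= 0:
        return np.zeros(U.shape[1])

    def fit(lam):
        if lam <= 0:
            return beta_ols
        m = Lasso(alpha=lam / (2 * len(y)), fit_intercept=False,
                  max_iter=500_000, tol=1e-12)
        m.fit(U, y)
        return m.coef_

    if np.abs(beta_ols).sum() <= target + tol:
        return beta_ols
    lo, hi = 0.0, 4 * np.abs(U.T @ y).max()
    for _ in range(200):
        mid = (lo + hi) / 2
        norm = np.abs(fit(mid)).sum()
        if norm > target:
            lo = mid
        else:
            hi = mid
    return fit((lo + hi) / 2)


class TestSelectCandidates:
    def _Z(self, vals):
        genes = [f"G{i+1}" for i in range(vals.shape[0])]
        return ConfidenceMatrix(genes, vals.astype(float))

    def test_all_zero_scores_give_empty_list(self):
        Z = self._Z(np.zeros((3, 3)))
        cand = select_candidates(Z, K=2)
        assert cand == {"G1": [], "G2": [], "G3": []}

    def test_top_k_by_score(self):
        vals = np.zeros((6, 6))
        vals[0, 1:] = [5, 1, 4, 2, 3]
        cand = select_candidates(self._Z(vals), K=3)
        assert cand["G1"] == ["G2", "G4", "G6"]

    def test_tie_at_rank_k_broken_by_index(self):
        vals = np.zeros((4, 4))
        vals[0, 1] = 2.0
        vals[0, 2] = 1.0
        vals[0, 3] = 1.0  # tie between G3 and G4 at rank 2
        cand = select_candidates(self._Z(vals), K=2)
        assert cand["G1"] == ["G2", "G3"]

    def test_mask_excludes_candidates(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = 2.0
        vals[0, 2] = 1.0
        mask = np.ones((3, 3), dtype=bool)
        mask[0, 1] = False
        cand = select_candidates(self._Z(vals), mask, K=2)
        assert cand["G1"] == ["G3"]


class TestLassoAtFraction:
    def test_s_one_recovers_ols(self, rng):
        U = _center_cols(rng.normal(size=(40, 5)))
        y = U @ rng.normal(size=5) + 0.1 * rng.normal(size=40)
        y = y - y.mean()
        beta_ols, *_ = np.linalg.lstsq(U, y, rcond=None)
        np.testing.assert_allclose(lasso_at_fraction(U, y, 1.0), beta_ols, atol=1e-8)

    def test_s_zero_gives_null_model(self, rng):
        U = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        np.testing.assert_array_equal(lasso_at_fraction(U, y, 0.0), 0.0)

    def test_single_predictor_binding_constraint(self, rng):
        # 1-D constrained least squares: beta = sign(b_ols) * s * |b_ols|
        u = rng.normal(size=30)
        u = (u - u.mean()) / np.std(u, ddof=1)
        y = 2.5 * u + 0.1 * rng.normal(size=30)
        y = y - y.mean()
        b_ols = float(u @ y / (u @ u))
        for s in (0.3, 0.6, 0.9):
            b = lasso_at_fraction(u[:, None], y, s)
            assert b[0] == pytest.approx(np.sign(b_ols) * s * abs(b_ols), abs=1e-10)

    def test_matches_coordinate_descent_oracle(self, rng):
        # 8 predictors, several constraint levels, tolerance 1e-6
        n, p = 60, 8
        U = _center_cols(rng.normal(size=(n, p)))
        beta_true = np.array([2.0, -1.5, 0.0, 0.0, 1.0, 0.0, 0.5, 0.0])
        y = U @ beta_true + 0.2 * rng.normal(size=n)
        y = y - y.mean()
        for s in (0.2, 0.5, 0.8, 1.0):
            ours = lasso_at_fraction(U, y, s)
            oracle = _oracle_constrained_lasso(U, y, s)
            np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_l1_norm_monotone_in_s(self, rng):
        U = _center_cols(rng.normal(size=(50, 6)))
        y = U @ rng.normal(size=6) + 0.3 * rng.normal(size=50)
        y = y - y.mean()
        norms = [
            np.abs(lasso_at_fraction(U, y, s)).sum()
            for s in np.linspace(0, 1, 21)
        ]
        assert all(b >= a - 1e-10 for a, b in zip(norms, norms[1:]))


class TestFitGeneModel:
    def test_strong_signal_selects_true_predictor(self, rng):
        n = 80
        U = rng.normal(size=(n, 4))
        U = (U - U.mean(axis=0)) / U.std(axis=0, ddof=1)
        y = 3.0 * U[:, 2] + 0.05 * rng.normal(size=n) + 7.0
        fit = fit_gene_model(y, U, gene="G1",
                             candidates=["G2", "G3", "G4", "G5"], seed=0)
        assert abs(fit.beta[2]) > 1.0
        assert fit.bias == pytest.approx(7.0, abs=0.1)
        assert fit.h > 0.9

    def test_constraint_respected_at_s_hat(self, rng):
        n = 60
        U = rng.normal(size=(n, 5))
        y = U @ rng.normal(size=5) + rng.normal(size=n)
        fit = fit_gene_model(y, U, seed=1)
        beta_ols, *_ = np.linalg.lstsq(
            U - U.mean(axis=0), y - y.mean(), rcond=None
        )
        assert np.abs(fit.beta).sum() <= fit.s_hat * np.abs(beta_ols).sum() + 1e-9

    def test_pure_noise_yields_sparse_null_model(self, rng):
        # one-SD rule on pure noise should pick a very small s
        n = 100
        U = rng.normal(size=(n, 6))
        y = rng.normal(size=n)
        fit = fit_gene_model(y, U, seed=2)
        assert fit.s_hat <= 0.3
        assert fit.h < 0.3

    def test_empty_candidates_bias_only(self, rng):
        y = rng.normal(size=30) + 5
        fit = fit_gene_model(y, np.empty((30, 0)), seed=3)
        assert fit.beta.size == 0
        assert fit.bias == pytest.approx(y.mean())
        assert fit.h == pytest.approx(0.0, abs=0.25)  # null model explains ~nothing

    def test_zero_variance_response_has_zero_power(self, rng):
        y = np.full(40, 2.0)
        fit = fit_gene_model(y, rng.normal(size=(40, 2)), seed=4)
        assert fit.h == 0.0

    def test_deterministic_given_seed(self, rng):
        U = rng.normal(size=(50, 3))
        y = U @ [1.0, -1.0, 0.5] + rng.normal(size=50)
        a = fit_gene_model(y, U, seed=7)
        b = fit_gene_model(y, U, seed=7)
        np.testing.assert_array_equal(a.beta, b.beta)
        assert a.s_hat == b.s_hat


class TestConfidences:
    def _fit(self, gene, candidates, beta, bias, h):
        return GeneFit(
            gene=gene, candidates=candidates, beta=np.asarray(beta, float),
            bias=bias, s_hat=1.0, cv_mean=np.zeros(1), cv_sd=np.zeros(1),
            s_grid=np.ones(1), h=h,
        )

    def test_single_regulator_zero_bias_full_power(self):
        fits = [self._fit("G1", ["G2"], [0.7], 0.0, 1.0)]
        Z = inferelator_confidences(fits, ["G1", "G2"])
        assert Z.values[0, 1] == pytest.approx(1.0)

    def test_weight_ratio_preserved(self):
        fits = [self._fit("G1", ["G2", "G3"], [3.0, -1.0], 0.0, 1.0)]
        Z = inferelator_confidences(fits, ["G1", "G2", "G3"])
        assert Z.values[0, 1] == pytest.approx(3 * Z.values[0, 2])

    def test_zero_power_zeroes_row(self):
        fits = [self._fit("G1", ["G2"], [0.7], 0.2, 0.0)]
        Z = inferelator_confidences(fits, ["G1", "G2"])
        assert np.all(Z.values[0] == 0)

    def test_bias_dilutes_confidence(self):
        fits = [self._fit("G1", ["G2"], [1.0], 1.0, 1.0)]
        Z = inferelator_confidences(fits, ["G1", "G2"])
        assert Z.values[0, 1] == pytest.approx(0.5)
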