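"""Inferelator-style L1-constrained regression on pre-selected candidates.

For each target gene the ODE response y_i is regressed on the standardized
expression of its top-K candidate regulators (candidates come from the
tlCLR confidence matrix, optionally pre-filtered by an MCZ mask) under the
constraint

    sum_j |beta_ij| <= s * sum_j |beta_ij^OLS|,

where s in [0, 1] is the shrinkage parameter: s = 1 recovers ordinary
least squares, s = 0 the bias-only null model. The constrained solution is
read off the LARS/lasso coefficient path. s is chosen by 10-fold
cross-validation with the one-standard-deviation rule (smallest s whose
mean CV error is within one sd of the minimum — the sparsest model that is
statistically indistinguishable from the best).

The cross-validated error also yields each model's *explanatory power*
h_i = 1 - (CV prediction SSE / total sum of squares), clipped to [0, 1],
which weights edge confidences: Z(i,j) = h_i |beta_ij| / (|beta_i0| +
sum_k |beta_ik|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import lars_path

from .datamodel import ConfidenceMatrix, DynamicalModel
from .design import ResponseDesign, standardize_explanatory

__all__ = [
    "GeneFit",
    "select_candidates",
    "lasso_at_fraction",
    "fit_gene_model",
    "fit_all_genes",
    "inferelator_confidences",
    "dynamical_model_from_fits",
]

DEFAULT_S_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass
class GeneFit:
    """One gene's constrained regression result."""

    gene: str
    candidates: list[str]
    beta: np.ndarray  # coefficients on standardized candidate regressors
    bias: float
    s_hat: float
    cv_mean: np.ndarray  # mean CV error (MSE) per grid s
    cv_sd: np.ndarray  # sd of CV error per grid s
    s_grid: np.ndarray
    h: float  # explanatory power in [0, 1]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.h = float(np.clip(self.h, 0.0, 1.0))


def select_candidates(
    Z_tlclr: ConfidenceMatrix,
    mcz_mask: np.ndarray | None = None,
    K: int = 10,
) -> dict[str, list[str]]:
    """Top-K nonzero-confidence regulators per target gene.

    Only entries with positive tlCLR score (and, when given, a true MCZ
    mask) qualify; sorted by score descending, ties broken by regulator
    index. A gene may end up with fewer than K (or zero) candidates.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    genes = Z_tlclr.gene_ids
    n = len(genes)
    if mcz_mask is None:
        mcz_mask = np.ones((n, n), dtype=bool)
    out: dict[str, list[str]] = {}
    for i, g in enumerate(genes):
        scores = Z_tlclr.values[i]
        eligible = [
            j for j in range(n) if j != i and scores[j] > 0 and mcz_mask[i, j]
        ]
        eligible.sort(key=lambda j: (-scores[j], j))
        out[g] = [genes[j] for j in eligible[:K]]
    return out


def _ols(U: np.ndarray, y: np.ndarray, ridge_eps: float = 1e-8) -> np.ndarray:
    """OLS coefficients (no intercept; U and y pre-centered), with a tiny
    ridge stabilization when the normal matrix is rank-deficient."""
    G = U.T @ U
    try:
        beta, *_ = np.linalg.lstsq(U, y, rcond=None)
        if np.linalg.matrix_rank(G) < G.shape[0]:
            raise np.linalg.LinAlgError
        return beta
    except np.linalg.LinAlgError:
        G = G + ridge_eps * np.eye(G.shape[0])
        return np.linalg.solve(G, U.T @ y)


class ConstrainedLassoPath:
    """LARS/lasso path of min ||y - U b||^2, queryable at any L1 budget.

    ``U`` (n_obs x n_pred) and ``y`` must be centered (no intercept term).
    Solutions at an arbitrary constraint ||b||_1 <= s * ||b_OLS||_1 are
    interpolated from the piecewise-linear coefficient path: within a path
    segment no coefficient changes sign, so the L1 norm is linear in the
    interpolation parameter.
    """

    def __init__(self, U: np.ndarray, y: np.ndarray) -> None:
        self.n_pred = U.shape[1]
        if self.n_pred == 0:
            self.ols_norm = 0.0
            self.coefs = np.zeros((0, 1))
            self.norms = np.zeros(1)
            return
        beta_ols = _ols(U, y)
        self.ols_norm = float(np.abs(beta_ols).sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, coefs = lars_path(U, y, method="lasso")
        self.coefs = coefs
        self.norms = np.abs(coefs).sum(axis=0)

    def at_fraction(self, s: float) -> np.ndarray:
        target = s * self.ols_norm
        if self.n_pred == 0 or target <= 0:
            return np.zeros(self.n_pred)
        norms, coefs = self.norms, self.coefs
        # first knot whose norm reaches the target (norms are non-decreasing
        # up to occasional drop events; scan finds the first crossing)
        reach = norms >= target
        if not reach.any():
            return coefs[:, -1].copy()
        k = int(np.argmax(reach))
        if k == 0:
            return coefs[:, 0].copy()
        lo, hi = norms[k - 1], norms[k]
        theta = 0.0 if hi == lo else (target - lo) / (hi - lo)
        return coefs[:, k - 1] + theta * (coefs[:, k] - coefs[:, k - 1])


def lasso_at_fraction(U: np.ndarray, y: np.ndarray, s: float) -> np.ndarray:
    """Coefficients of min ||y - U b||^2 s.t. ||b||_1 <= s * ||b_OLS||_1."""
    return ConstrainedLassoPath(U, y).at_fraction(s)


def _cv_folds(n_obs: int, k_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Contiguous folds over a seeded shuffle of the observation indices."""
    perm = rng.permutation(n_obs)
    return [np.sort(chunk) for chunk in np.array_split(perm, k_folds)]


def fit_gene_model(
    y: np.ndarray,
    U: np.ndarray,
    gene: str = "",
    candidates: list[str] | None = None,
    k_folds: int = 10,
    s_grid: np.ndarray | None = None,
    seed: int = 0,
) -> GeneFit:
    """Cross-validated constrained fit for one gene.

    ``y`` is the response vector (not standardized — its scale carries the
    degradation rate), ``U`` the n_obs x n_candidates matrix of
    standardized regulator observations.
    """
    y = np.asarray(y, dtype=float)
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    n_obs = y.size
    if U.shape[0] != n_obs:
        raise ValueError("response/design length mismatch")
    if n_obs < k_folds:
        raise ValueError(f"need >= {k_folds} observations for {k_folds}-fold CV")
    if s_grid is None:
        s_grid = DEFAULT_S_GRID
    s_grid = np.asarray(s_grid, dtype=float)
    candidates = list(candidates) if candidates is not None else []
    rng = np.random.default_rng(seed)
    folds = _cv_folds(n_obs, k_folds, rng)

    tss = float(((y - y.mean()) ** 2).sum())
    fold_mse = np.zeros((k_folds, s_grid.size))
    fold_sse = np.zeros((k_folds, s_grid.size))
    for f, val_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(n_obs), val_idx)
        y_tr, y_val = y[train], y[val_idx]
        U_tr, U_val = U[train], U[val_idx]
        mu = y_tr.mean()
        path = ConstrainedLassoPath(U_tr, y_tr - mu)
        for si, s in enumerate(s_grid):
            b = path.at_fraction(s)
            pred = mu + U_val @ b
            sse = float(((y_val - pred) ** 2).sum())
            fold_sse[f, si] = sse
            fold_mse[f, si] = sse / val_idx.size
    cv_mean = fold_mse.mean(axis=0)
    cv_sd = fold_mse.std(axis=0, ddof=1)
    i_min = int(np.argmin(cv_mean))
    threshold = cv_mean[i_min] + cv_sd[i_min]
    i_hat = int(np.nonzero(cv_mean <= threshold)[0][0])  # smallest feasible s
    s_hat = float(s_grid[i_hat])

    # final fit on all data at s_hat
    mu = y.mean()
    beta = lasso_at_fraction(U, y - mu, s_hat)

    cv_sse_hat = float(fold_sse[:, i_hat].sum())
    if tss <= 0:
        h = 0.0
    else:
        h = float(np.clip(1.0 - cv_sse_hat / tss, 0.0, 1.0))
    return GeneFit(
        gene=gene,
        candidates=candidates,
        beta=beta,
        bias=float(mu),
        s_hat=s_hat,
        cv_mean=cv_mean,
        cv_sd=cv_sd,
        s_grid=s_grid,
        h=h,
    )


def fit_all_genes(
    rd: ResponseDesign,
    candidates: dict[str, list[str]],
    k_folds: int = 10,
    s_grid: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[list[GeneFit], np.ndarray, np.ndarray]:
    """Fit every gene's model; returns fits plus the regressor mean/sd used
    to standardize the explanatory rows."""
    X_std, mean, sd, constant = standardize_explanatory(rd.X)
    idx = {g: k for k, g in enumerate(rd.gene_ids)}
    fits = []
    for i, g in enumerate(rd.gene_ids):
        cand = [c for c in candidates.get(g, []) if not constant[idx[c]]]
        cols = [idx[c] for c in cand]
        U = X_std[cols, :].T if cols else np.empty((rd.n_obs, 0))
        fit = fit_gene_model(
            rd.Y[i],
            U,
            gene=g,
            candidates=cand,
            k_folds=k_folds,
            s_grid=s_grid,
            seed=seed + i,
        )
        fits.append(fit)
    return fits, mean, sd


def inferelator_confidences(
    fits: list[GeneFit], gene_ids: list[str]
) -> ConfidenceMatrix:
    """Explanatory-power-weighted coefficient shares as edge confidences."""
    idx = {g: k for k, g in enumerate(gene_ids)}
    n = len(gene_ids)
    Z = np.zeros((n, n))
    for fit in fits:
        i = idx[fit.gene]
        denom = abs(fit.bias) + np.abs(fit.beta).sum()
        if denom == 0:
            continue
        for c, b in zip(fit.candidates, fit.beta):
            Z[i, idx[c]] = fit.h * abs(b) / denom
    return ConfidenceMatrix(list(gene_ids), Z)


def dynamical_model_from_fits(
    fits: list[GeneFit],
    gene_ids: list[str],
    alpha: float,
    regressor_mean: np.ndarray,
    regressor_sd: np.ndarray,
) -> DynamicalModel:
    idx = {g: k for k, g in enumerate(gene_ids)}
    n = len(gene_ids)
    beta = np.zeros((n, n))
    bias = np.zeros(n)
    h = np.zeros(n)
    for fit in fits:
        i = idx[fit.gene]
        bias[i] = fit.bias
        h[i] = fit.h
        for c, b in zip(fit.candidates, fit.beta):
            beta[i, idx[c]] = b
    return DynamicalModel(
        gene_ids=list(gene_ids),
        beta=beta,
        bias=bias,
        h=h,
        alpha=alpha,
        regressor_mean=np.asarray(regressor_mean, dtype=float),
        regressor_sd=np.asarray(regressor_sd, dtype=float),
    )
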