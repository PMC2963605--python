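"""ODE-derived response/explanatory design shared by tlCLR and the lasso.

The temporal change of each gene is modelled by the linear ODE
dx_i/dt = sum_j beta_ij x_j - alpha x_i with a common first-order
degradation rate alpha = ln(2)/tau_half. A finite-difference
approximation over intervals of length L*dt (lags L = 1, 2) turns each
time-series interval into a response observation

    y_i(t) = (x_i(t + L*dt) - x_i(t)) / (L*dt) + alpha * x_i(t)

paired with the *time-lagged* explanatory value x_j(t). At steady state
the derivative vanishes and every steady-state condition contributes
y_i = alpha * x_i paired with x_j from the same condition. Responses and
explanatory values are stored as two aligned genes x observations
matrices; explanatory rows are standardized (zero mean, unit sd) before
model selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Iterable, Sequence

import numpy as np

from .datamodel import ExpressionMatrix, TimeSeriesSet

__all__ = ["ResponseDesign", "build_response_design", "standardize_explanatory"]

DEFAULT_TAU_HALF = 50.0


@dataclass
class ResponseDesign:
    """Aligned response (Y) and explanatory (X) matrices, genes x observations.

    ``obs_kind`` tags each column: ``ts_lag1`` / ``ts_lag2`` for
    time-series intervals, ``steady`` for steady-state conditions.
    """

    gene_ids: list[str]
    Y: np.ndarray
    X: np.ndarray
    obs_kind: list[str]
    alpha: float
    tau_half: float

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.Y.shape != self.X.shape:
            raise ValueError("Y and X must share shape/column alignment")
        if self.Y.shape[1] != len(self.obs_kind):
            raise ValueError("obs_kind must tag every column")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return self.Y.shape[1]

    def subset_columns(self, idx: np.ndarray) -> "ResponseDesign":
        """Columns re-indexed by ``idx`` (used by the bootstrap); pairing kept."""
        idx = np.asarray(idx)
        return ResponseDesign(
            gene_ids=list(self.gene_ids),
            Y=self.Y[:, idx],
            X=self.X[:, idx],
            obs_kind=[self.obs_kind[k] for k in idx],
            alpha=self.alpha,
            tau_half=self.tau_half,
        )


def build_response_design(
    ts: TimeSeriesSet | None,
    ss_blocks: Sequence[ExpressionMatrix] = (),
    tau_half: float = DEFAULT_TAU_HALF,
    lags: Iterable[int] = (1, 2),
    alpha_convention: str = "half_life",
) -> ResponseDesign:
    """Assemble the response/explanatory design from time series and
    steady-state blocks (typically [KO, KD, WT], merged).

    ``alpha_convention`` maps the tau constant to the degradation rate:
    ``"half_life"`` (default) uses alpha = ln(2)/tau_half, ``"time_constant"``
    uses alpha = 1/tau_half. Series shorter than a lag simply skip that lag.
    """
    lags = sorted(set(int(L) for L in lags))
    if any(L not in (1, 2) for L in lags):
        raise ValueError("lags must be a subset of {1, 2}")
    if alpha_convention == "half_life":
        alpha = log(2.0) / tau_half
    elif alpha_convention == "time_constant":
        alpha = 1.0 / tau_half
    else:
        raise ValueError("alpha_convention must be 'half_life' or 'time_constant'")

    gene_ids: list[str] | None = None
    if ts is not None:
        gene_ids = list(ts.gene_ids)
    for blk in ss_blocks:
        if gene_ids is None:
            gene_ids = list(blk.gene_ids)
        elif blk.gene_ids != gene_ids:
            raise ValueError("all blocks must share gene order")
    if gene_ids is None:
        raise ValueError("no data supplied")

    y_cols, x_cols, kinds = [], [], []
    if ts is not None:
        for exp in ts.experiments:
            dt = exp.dt
            T = exp.n_timepoints
            for L in lags:
                if T < L + 1:
                    continue
                for t in range(T - L):
                    x_t = exp.matrix[:, t]
                    x_next = exp.matrix[:, t + L]
                    y_cols.append((x_next - x_t) / (L * dt) + alpha * x_t)
                    x_cols.append(x_t)
                    kinds.append(f"ts_lag{L}")
    for blk in ss_blocks:
        for c in range(blk.n_conditions):
            x = blk.values[:, c]
            y_cols.append(alpha * x)
            x_cols.append(x)
            kinds.append("steady")
    if not y_cols:
        raise ValueError("design is empty: no usable observations")
    Y = np.column_stack(y_cols)
    X = np.column_stack(x_cols)
    return ResponseDesign(gene_ids, Y, X, kinds, alpha, tau_half)


def standardize_explanatory(
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise standardization to zero mean / unit sd.

    Returns ``(X_std, mean, sd, constant_mask)``. Constant rows (sd = 0)
    are flagged and left untouched (sd reported as 0); they are excluded
    from candidate regressors downstream.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    X_std = (X - mean[:, None]) / safe_sd[:, None]
    X_std[constant, :] = X[constant, :]
    mean = np.where(constant, 0.0, mean)
    return X_std, mean, np.where(constant, 0.0, sd), constant
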