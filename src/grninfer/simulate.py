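"""DREAM4-style in-silico benchmark generator.

Generates sparse signed regulatory topologies and simulates them with a
saturating-production ODE,

    dx_i/dt = m_i * sigma(sum_j w_ij x_j + b_i) - alpha_i x_i,

where ``sigma`` is the logistic function, ``m_i`` a per-gene basal
transcription rate and ``alpha_i`` a first-order degradation rate. A
knock-out sets ``m_i = 0`` (so the knocked-out gene decays to exactly 0), a
knock-down halves it. The released data blocks mirror the DREAM4 design:

* 1 wild-type profile + the first observation of each time series,
* per-gene knock-out and knock-down steady states,
* ``n_series`` perturbation/relaxation time-series pairs (a random subset
  of basal rates is shifted for the perturbation phase, then restored),
* noise-free double knock-out steady states for a set of random gene pairs,
* the gold-standard topology (nonzero pattern of the weight matrix).

Observational noise is proportional to expression, ``x <- max(0,
x*(1 + c*eps) + floor*eps')`` with standard-normal ``eps, eps'``, applied to
every released block except the double-knock-out truth.

The module also provides a *linear* forward-Euler generator
(:func:`euler_linear_series`) whose observations satisfy the package's
finite-difference response model algebraically — the identifiability
oracle used by the regression tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.integrate import solve_ivp

from .datamodel import (
    ExpressionMatrix,
    GoldStandard,
    KnockoutMap,
    TimeSeriesExperiment,
    TimeSeriesSet,
    default_gene_ids,
)

__all__ = [
    "SyntheticNetwork",
    "SimulationConfig",
    "Dream4Dataset",
    "generate_topology",
    "simulate_steady_state",
    "simulate_dream4_dataset",
    "euler_linear_series",
    "linear_steady_state",
]

DEFAULT_TAU_HALF = 50.0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically safe logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class SyntheticNetwork:
    """A signed sparse topology plus the kinetic parameters that drive it.

    ``adjacency[i, j]`` is the signed weight of regulator j on target i
    (zero = no edge, no self-edges). ``basal`` are the basal transcription
    rates m_i > 0, ``bias`` the sigmoid offsets b_i, ``decay`` the
    degradation rates (default ln2 / tau_half).
    """

    n_genes: int
    adjacency: np.ndarray
    basal: np.ndarray
    bias: np.ndarray
    decay: np.ndarray
    seed: int | None = None
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.basal = np.asarray(self.basal, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        self.decay = np.asarray(self.decay, dtype=float)
        if not self.gene_ids:
            self.gene_ids = default_gene_ids(self.n_genes)
        if self.adjacency.shape != (self.n_genes, self.n_genes):
            raise ValueError("adjacency must be N x N")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-edges are not allowed")

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))

    def gold_standard(self) -> GoldStandard:
        edges = {
            (self.gene_ids[j], self.gene_ids[i])
            for i, j in zip(*np.nonzero(self.adjacency))
        }
        return GoldStandard(list(self.gene_ids), edges)


@dataclass
class SimulationConfig:
    """Study-design knobs for the DREAM4-style dataset.

    Defaults mirror the DREAM4 design: 10 perturbation/relaxation series,
    11 points per phase at spacing 50 (arbitrary time units), per-gene KO
    and KD blocks, 20 double-knock-out pairs, noise proportional to
    expression with coefficient 0.1.
    """

    n_series: int = 10
    points_per_phase: int = 11
    dt: float = 50.0
    noise_coeff: float = 0.1
    noise_floor: float = 0.01
    kd_factor: float = 0.5
    n_double_ko: int = 20
    perturbed_fraction: float = 1.0 / 3.0
    perturb_log_range: tuple[float, float] = (0.25, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.noise_coeff < 0:
            raise ValueError("noise_coeff must be >= 0")
        if not (0 < self.kd_factor < 1):
            raise ValueError("kd_factor must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_series": self.n_series,
            "points_per_phase": self.points_per_phase,
            "dt": self.dt,
            "noise_coeff": self.noise_coeff,
            "noise_floor": self.noise_floor,
            "kd_factor": self.kd_factor,
            "n_double_ko": self.n_double_ko,
            "perturbed_fraction": self.perturbed_fraction,
            "perturb_log_range": list(self.perturb_log_range),
            "seed": self.seed,
        }


@dataclass
class Dream4Dataset:
    """Everything one synthetic benchmark releases (plus the hidden truth)."""

    ts: TimeSeriesSet
    wt: ExpressionMatrix
    ko: ExpressionMatrix
    kd: ExpressionMatrix
    komap: KnockoutMap
    kdmap: KnockoutMap
    double_ko: list[tuple[tuple[str, str], np.ndarray]]
    gold: GoldStandard
    config: SimulationConfig
    network: SyntheticNetwork | None = None

    @property
    def gene_ids(self) -> list[str]:
        return self.ts.gene_ids


def generate_topology(
    n_genes: int,
    mean_in_degree: float = 2.0,
    seed: int | None = 0,
    activation_fraction: float = 0.7,
    weight_range: tuple[float, float] = (0.5, 2.0),
    basal_scale_range: tuple[float, float] = (0.25, 4.0),
    tau_half: float = DEFAULT_TAU_HALF,
) -> SyntheticNetwork:
    """Draw a random sparse signed topology with kinetic parameters.

    Each of the N(N-1) candidate directed pairs becomes an edge
    independently with probability ``mean_in_degree / (n_genes - 1)``;
    signs are activating with probability ``activation_fraction``, weight
    magnitudes uniform in ``weight_range``. Basal rates are heterogeneous:
    each gene gets a target expression scale log-uniform in
    ``basal_scale_range`` and ``m_i = 2 * alpha_i * scale_i`` (so an
    isolated gene with b_i = 0 sits near its scale).
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if mean_in_degree >= n_genes - 1:
        raise ValueError("mean_in_degree must be < n_genes - 1")
    rng = np.random.default_rng(seed)
    p_edge = mean_in_degree / (n_genes - 1)
    mask = rng.random((n_genes, n_genes)) < p_edge
    np.fill_diagonal(mask, False)
    signs = np.where(rng.random((n_genes, n_genes)) < activation_fraction, 1.0, -1.0)
    mags = rng.uniform(weight_range[0], weight_range[1], size=(n_genes, n_genes))
    adjacency = np.where(mask, signs * mags, 0.0)
    alpha = math.log(2.0) / tau_half
    lo, hi = np.log(basal_scale_range[0]), np.log(basal_scale_range[1])
    scales = np.exp(rng.uniform(lo, hi, size=n_genes))
    basal = 2.0 * alpha * scales
    bias = rng.normal(0.0, 1.0, size=n_genes)
    decay = np.full(n_genes, alpha)
    return SyntheticNetwork(
        n_genes=n_genes,
        adjacency=adjacency,
        basal=basal,
        bias=bias,
        decay=decay,
        seed=seed,
    )


def _effective_basal(
    net: SyntheticNetwork,
    ko_genes: Iterable[str] = (),
    kd_genes: Iterable[str] = (),
    kd_factor: float = 0.5,
    basal_factors: np.ndarray | None = None,
) -> np.ndarray:
    idx = {g: k for k, g in enumerate(net.gene_ids)}
    m = net.basal.copy()
    if basal_factors is not None:
        m = m * basal_factors
    for g in kd_genes:
        m[idx[g]] *= kd_factor
    for g in ko_genes:
        m[idx[g]] = 0.0
    return m


def _rhs(net: SyntheticNetwork, m: np.ndarray):
    W, b, alpha = net.adjacency, net.bias, net.decay

    def f(t, x):
        return m * _sigmoid(W @ x + b) - alpha * x

    return f


def simulate_steady_state(
    net: SyntheticNetwork,
    ko_genes: Iterable[str] = (),
    kd_genes: Iterable[str] = (),
    kd_factor: float = 0.5,
    basal_factors: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Equilibrate the network and return the steady-state expression.

    Integrates the ODE to near-equilibrium, then polishes with a damped
    fixed-point iteration on x = m*sigma(Wx+b)/alpha until
    ``max |dx/dt| < tol``. Knock-out genes end at exactly 0.
    """
    m = _effective_basal(net, ko_genes, kd_genes, kd_factor, basal_factors)
    alpha = net.decay
    f = _rhs(net, m)
    if x0 is None:
        x = m * _sigmoid(net.bias) / alpha
    else:
        x = np.asarray(x0, dtype=float).copy()
    # coarse integration: a few half-life multiples
    t_end = 20.0 / float(np.min(alpha))
    sol = solve_ivp(f, (0.0, t_end), x, method="LSODA", rtol=1e-8, atol=1e-10)
    x = sol.y[:, -1]
    # damped fixed-point polish
    gamma = 0.5
    for _ in range(max_iter):
        resid = f(0.0, x)
        if np.max(np.abs(resid)) < tol:
            break
        x = x + gamma * resid / alpha
    else:
        raise RuntimeError(
            f"steady state did not converge below {tol} "
            f"(ko={sorted(ko_genes)}, kd={sorted(kd_genes)})"
        )
    x = np.maximum(x, 0.0)
    idx = {g: k for k, g in enumerate(net.gene_ids)}
    for g in ko_genes:
        x[idx[g]] = 0.0
    return x


def _integrate_series(
    net: SyntheticNetwork,
    m: np.ndarray,
    x0: np.ndarray,
    n_points: int,
    dt: float,
) -> np.ndarray:
    """Integrate and sample at 0, dt, ..., (n_points-1)*dt. Returns genes x points."""
    f = _rhs(net, m)
    t_eval = np.arange(n_points) * dt
    sol = solve_ivp(
        f,
        (0.0, float(t_eval[-1])),
        np.asarray(x0, dtype=float),
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"time-series integration failed: {sol.message}")
    return sol.y


def _apply_noise(values: np.ndarray, cfg: SimulationConfig, rng) -> np.ndarray:
    if cfg.noise_coeff == 0 and cfg.noise_floor == 0:
        return values.copy()
    eps = rng.standard_normal(values.shape)
    eps2 = rng.standard_normal(values.shape)
    noisy = values * (1.0 + cfg.noise_coeff * eps) + cfg.noise_floor * eps2
    return np.maximum(noisy, 0.0)


def simulate_dream4_dataset(
    net: SyntheticNetwork, config: SimulationConfig | None = None
) -> Dream4Dataset:
    """Simulate the full DREAM4-style data release for one network."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = net.gene_ids
    n = net.n_genes

    wt_ss = simulate_steady_state(net)

    # time series: perturbation phase then relaxation phase, separate blocks
    experiments: list[np.ndarray] = []
    first_points: list[np.ndarray] = []
    n_perturbed = max(1, int(round(cfg.perturbed_fraction * n)))
    lo, hi = np.log(cfg.perturb_log_range[0]), np.log(cfg.perturb_log_range[1])
    for _ in range(cfg.n_series):
        subset = rng.choice(n, size=n_perturbed, replace=False)
        factors = np.ones(n)
        factors[subset] = np.exp(rng.uniform(lo, hi, size=n_perturbed))
        m_pert = _effective_basal(net, basal_factors=factors)
        pert = _integrate_series(net, m_pert, wt_ss, cfg.points_per_phase, cfg.dt)
        relax = _integrate_series(
            net, net.basal, pert[:, -1], cfg.points_per_phase, cfg.dt
        )
        experiments.append(pert)
        experiments.append(relax)
        first_points.append(pert[:, 0])

    # steady-state blocks
    ko_cols = np.column_stack(
        [simulate_steady_state(net, ko_genes=[g]) for g in genes]
    )
    kd_cols = np.column_stack(
        [
            simulate_steady_state(net, kd_genes=[g], kd_factor=cfg.kd_factor)
            for g in genes
        ]
    )
    wt_cols = np.column_stack(first_points + [wt_ss])

    # double knock-outs (noise-free truth)
    pairs_idx = set()
    while len(pairs_idx) < cfg.n_double_ko:
        a, b = rng.choice(n, size=2, replace=False)
        pairs_idx.add((min(a, b), max(a, b)))
    double_ko = []
    for a, b in sorted(pairs_idx):
        truth = simulate_steady_state(net, ko_genes=[genes[a], genes[b]])
        double_ko.append(((genes[a], genes[b]), truth))

    # observational noise on every released block
    t_eval = np.arange(cfg.points_per_phase) * cfg.dt
    ts = TimeSeriesSet(
        list(genes),
        [
            TimeSeriesExperiment(t_eval, _apply_noise(mat, cfg, rng))
            for mat in experiments
        ],
    )
    wt = ExpressionMatrix(
        list(genes),
        [f"wt{k + 1}" for k in range(wt_cols.shape[1])],
        _apply_noise(wt_cols, cfg, rng),
    )
    ko = ExpressionMatrix(
        list(genes), [f"KO_{g}" for g in genes], _apply_noise(ko_cols, cfg, rng)
    )
    kd = ExpressionMatrix(
        list(genes), [f"KD_{g}" for g in genes], _apply_noise(kd_cols, cfg, rng)
    )
    komap = KnockoutMap({g: k for k, g in enumerate(genes)})
    kdmap = KnockoutMap({g: k for k, g in enumerate(genes)})
    return Dream4Dataset(
        ts=ts,
        wt=wt,
        ko=ko,
        kd=kd,
        komap=komap,
        kdmap=kdmap,
        double_ko=double_ko,
        gold=net.gold_standard(),
        config=cfg,
        network=net,
    )


# ---------------------------------------------------------------------------
# linear dynamics helpers (identifiability oracle)
# ---------------------------------------------------------------------------

def euler_linear_series(
    net: SyntheticNetwork,
    x0: np.ndarray,
    n_points: int,
    dt: float,
) -> np.ndarray:
    """Forward-Euler observations of the linear dynamics
    dx/dt = m + W x - alpha x at the measurement spacing.

    Because the discrete update is x(t+dt) = x(t) + dt*(m + W x - alpha x),
    the lag-1 finite-difference response (x(t+dt)-x(t))/dt + alpha*x(t)
    equals m + W x(t) *exactly* — these series make the linear regression
    stage exactly identifiable, which is what the oracle tests need.
    """
    x = np.asarray(x0, dtype=float).copy()
    out = np.empty((net.n_genes, n_points))
    out[:, 0] = x
    for k in range(1, n_points):
        x = x + dt * (net.basal + net.adjacency @ x - net.decay * x)
        out[:, k] = x
    return out


def linear_steady_state(
    net: SyntheticNetwork, ko_genes: Iterable[str] = ()
) -> np.ndarray:
    """Exact steady state of the linear dynamics with KO genes pinned to 0.

    Non-KO genes satisfy alpha x = m + W x restricted to the free block.
    """
    idx = {g: k for k, g in enumerate(net.gene_ids)}
    ko = sorted(idx[g] for g in ko_genes)
    free = [k for k in range(net.n_genes) if k not in ko]
    A = np.diag(net.decay)[np.ix_(free, free)] - net.adjacency[np.ix_(free, free)]
    x = np.zeros(net.n_genes)
    x[free] = np.linalg.solve(A, net.basal[free])
    return x
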