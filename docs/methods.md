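# Methods

This note documents the models, estimators and design choices behind
`grninfer`, the defaults that matter, and what the synthetic benchmark
does and does not establish about real data.

## Data design

All pipelines operate on the DREAM4-style data release for an N-gene
system:

* `X^wt` — wild-type observations: the first time point of each of the
  `n_series` time series (10 by default) plus one dedicated wild-type
  profile, 11 columns in total;
* `X^ko`, `X^kd` — steady states after setting each gene's transcription
  rate to 0 (knock-out) or half (knock-down), one column per gene;
* `X^ts` — time series sampled at a constant interval Δ (50 arbitrary
  time units by default). Each series has a perturbation phase and a
  relaxation phase after the perturbation is removed; the two phases are
  treated as separate experiments, so no finite difference ever spans the
  boundary.

## Pipeline 1: median-corrected z-scores (MCZ)

For sparse networks most single-KO columns are effectively independent
wild-type measurements of most genes, so the wild-type level of gene i is
estimated as the median x̃_i over the concatenated WT and KO columns;
the median is preferred to the mean for outlier robustness. The score of
edge j → i is |x_i^(KO j) − x̃_i| / σ_i with σ_i the *sample* standard
deviation (ddof = 1; the choice is inconsequential for the ranking,
which is scale-equivariant per row) over the same columns.

Choices worth recording:

* The self-KO column is included in each gene's median/σ by default
  (it is one of the pooled columns); an `exclude_self_ko` option drops
  it, since the self-KO is guaranteed non-wild-type. With 100+ columns
  the difference is negligible.
* σ_i = 0 (constant gene): entries with zero deviation score 0; entries
  with nonzero deviation receive the largest finite score in the matrix
  plus 1 — a sentinel that preserves the ranking without infinities.
* Before combining MCZ with the time-series pipelines, edges in the
  lower tail of the MCZ distribution are removed. The percentile is a
  free parameter (default 20, configurable); the mask keeps entries
  *strictly above* the percentile cutoff, so an all-tied matrix keeps
  nothing.

## The ODE response design

Dynamics are modelled as dx_i/dt = Σ_j β_ij x_j − α x_i with one global
first-order degradation rate α. The time constant is parameterized by an
mRNA half-life τ½ = 50 (the measurement interval), α = ln 2 / τ½ ≈ 0.0139
per time unit. Because "the constant 50" could equally be read as the
time constant 1/α, the alternative convention (α = 1/τ) is exposed as
`alpha_convention="time_constant"`; the two differ by a factor ln 2 and
leave all rank-based results nearly unchanged.

Each time-series interval of length LΔ (lags L ∈ {1, 2}; longer lags add
little dynamic information) contributes a response column
y_i = (x_i(t+LΔ) − x_i(t))/(LΔ) + α x_i(t) paired with the *time-lagged*
explanatory value x_j(t); the α-term uses the left endpoint, and the
prediction stage inverts the same convention. Steady-state conditions
(KO + KD + WT merged) contribute y_i = α x_i paired with x_j from the
same condition. For one 11-point series both lags together give
10 + 9 = 19 columns; a DREAM4-sized dataset (10 series × 2 phases + 211
steady columns at N = 100) yields 591 aligned observation columns.

Explanatory rows are standardized to zero mean and unit sample sd before
model selection; constant rows are flagged and excluded from candidate
regressors. The response is *not* standardized — its scale carries α.

## Pipeline 2: tlCLR + constrained regression

**Mutual information.** MI is estimated by a plug-in estimator on
equal-frequency (quantile) discretizations, 10 bins per variable,
base-2 logarithm. Binning is rank-based with stable tie resolution
(observation k in sorted order goes to bin ⌊k·B/n⌋), which makes the
estimator deterministic and invariant under monotone transforms. The
plug-in estimator's positive bias (~(B−1)²/(2n ln 2) bits) cancels in
the z-scoring step; consistency is verified against the closed form
−½ log₂(1−ρ²) for bivariate Gaussians.

**Background correction.** Static MI (MI(x_i, x_j) over all observation
columns, symmetric) and dynamic MI (MI(y_i, x_j), asymmetric — this is
what orients edges) feed two clipped z-scores: z₁ scores M_dyn(i, j)
against row i of M_dyn, z₂ against column j of M_stat. Negatives are set
to 0 and the final score is √(z₁² + z₂²), the root-sum-square
combination used in the CLR family. Zero row/column sd makes that
contribution 0. The clipping leaves a sizeable fraction of exact zeros,
which downstream stages exploit.

**Constrained lasso.** For each gene the K = 10 highest-confidence
nonzero tlCLR regulators (after the MCZ mask) are candidates. The fit
minimizes the squared response error subject to ‖β‖₁ ≤ s·‖β^OLS‖₁,
solved by interpolating the LARS/lasso coefficient path (within a path
segment no coefficient changes sign, so the L1 norm is linear in the
interpolation parameter). s is selected from the grid {0, 0.05, …, 1} by
10-fold cross-validation — contiguous folds over a seeded shuffle of the
observation columns — using the one-standard-deviation rule in the
*sparse* direction: the smallest s whose mean CV error is within one sd
of the minimum. s = 1 reproduces OLS; s = 0 the bias-only model.
Rank-deficient OLS reference norms fall back to a ridge-stabilized
solve (ε = 1e−8).

**Explanatory power and confidences.** h_i = clip(1 − CV-SSE(ŝ)/TSS, 0, 1)
uses the cross-validated error at the selected s (not a refit). Edge
confidences are Z(i, j) = h_i·|β_ij| / (|β_i0| + Σ_k |β_ik|) — a
coefficient's share of the model, discounted by model quality; this
relies on the regulators being standardized, which puts all |β| on one
scale.

**Rank transplant.** To combine two confidence matrices on incompatible
scales, the k-th largest nonzero entry of B receives the k-th largest
off-diagonal value of the reference A (deterministic (regulator, target)
tie-breaks), after which the matrices are summed element-wise. The sum
is one of several monotone combinations with identical rankings; it is
used for its simplicity. Pipeline 2 uses tlCLR as the reference for the
regression confidences; pipeline 3 uses MCZ as the reference for the
pipeline-2 result.

## Pipeline 4: bootstrap ensemble

The response/explanatory columns are resampled with replacement
(pairing preserved), and tlCLR → lasso → combination with the *fixed*
MCZ matrix is re-run per resample, with per-member seeds seed+m for
reproducible (and embarrassingly parallel) execution. Aggregation is by
median rank: each member's off-diagonal entries are ranked (average
ranks on ties) and an edge's final confidence is P + 1 − median rank.
Dynamical parameters are aggregated entry-wise by median with zeros
included — an edge must appear in at least half the members to survive,
which keeps the ensemble model sparse. Medianing over *transplanted
scores* instead of ranks is available behind `use_scores=True`.
M = 200 resamples is the default; the qualitative AUPR ordering is
already stable at a few dozen members, which is what the test suite
uses (M = 25) to keep runtimes down.

## Double-knock-out prediction

At steady state the fitted model gives x̂_i = (β_i0 + Σ_j β_ij u_j)/α,
with u the standardized initial-condition vector. This is a *single
evaluation* at x₀, not a fixed-point solve (an optional damped iteration
is available behind `fixed_point_iterations`). Initial conditions:

* `wildtype` — the released wild-type observation with the pair zeroed
  (the median-corrected estimate can be passed explicitly instead);
* `single_ko_mean` — the mean of the two single-KO columns;
* `single_ko_weighted` (default) — the MCZ-weighted average
  x0_i = (Z(i,p)·x_i^(KO p) + Z(i,q)·x_i^(KO q)) / (Z(i,p) + Z(i,q)),
  falling back to the plain mean where both weights vanish. A gene
  confidently regulated by p follows p's knock-out profile — the state
  closest to the double-KO state being predicted.

The released prediction blends model and initial conditions by
explanatory power, x_final = h·x̂ + (1 − h)·x₀ (genes whose models are
untrustworthy stay at their initial conditions), clamped nonnegative
with the knocked-out pair pinned to 0. Accuracy is mean squared error
against the noise-free truth over all genes (the 0-vs-0 KO entries count
in the denominator).

## The synthetic benchmark

The generator emulates the DREAM4 study design rather than its exact
kinetic simulator: deterministic ODE dynamics
dx_i/dt = m_i σ(Σ_j w_ij x_j + b_i) − α x_i with a logistic σ, plus
*observational* noise proportional to expression,
x ← max(0, x(1 + c·ε) + floor·ε′), c = 0.1, floor = 0.01. The bounded
production keeps random topologies stable and makes KO/KD effects
saturate realistically; a knock-out (m_i = 0) drives its gene to exactly
0. Intrinsic (stochastic kinetic) noise and organism-motif topology
structure are *not* emulated.

Topologies are Erdős–Rényi-style directed graphs: each ordered pair is
an edge with probability mean-in-degree/(N−1) (default mean in-degree 2,
so ≈ 2N edges), 70 % activating, weight magnitudes uniform in
[0.5, 2.0]. Basal rates are heterogeneous — per-gene expression scales
log-uniform over a 16-fold range — which is what produces the
expression-dependent difficulty of knock-out-based inference seen in the
evaluation. Time-series perturbations multiply the basal rates of a
random third of genes by log-uniform factors in [0.25, 4]; the
perturbation phase starts from the wild-type steady state and the
relaxation phase from the perturbed end state.

Steady states are found by integrating the ODE (LSODA) and polishing
with a damped fixed-point iteration to max |dx/dt| < 1e−9; double-KO
truths are released noise-free. Everything derives from a single seed
and is bit-reproducible.

A separate linear forward-Euler generator (`euler_linear_series`) exists
for verification: because its discrete update matches the
finite-difference response algebraically, regression on its output is
*exactly* identifiable (Y = B·X + bias to machine precision), which
anchors the parameter-recovery tests. Its companion
`linear_steady_state` solves the linear balance with KO genes pinned
to 0.

## What the tests do and do not show

The suite verifies, at desk scale (10–20 genes, 10 seeds, c = 0.1):

* exact structural constants (perfect-ranking AUPR = 1; 11 WT columns;
  20 double-KO pairs per network, 100 over five networks);
* oracle equivalence of every scoring stage (MCZ vs brute-force
  median/σ; MI vs an independent pairwise estimator; the constrained
  lasso vs a coordinate-descent/bisection oracle; AUPR vs a threshold
  sweep);
* exact parameter recovery and the double-KO fixed-point property on
  linear data;
* the qualitative orderings: ensemble ≥ combined ≥ dynamic-only median
  AUPR; MCZ error growing toward low-expression regulators; single-KO
  initial conditions beating wild-type ones; and the blended model
  beating the wild-type initial-condition baseline in a majority of
  pairs.

Because the generator is a deterministic-ODE emulation with
observational noise only, these results demonstrate correct mechanics
and the expected *relative* behaviour of the pipelines — not absolute
performance on data from stochastic kinetic simulators or real
organisms. Two desk-scale limitations are known: (i) a random ranking's
mean AUPR sits slightly *above* the edge density at small P (precision
is bounded below by zero early in the list), so "random ≈ density" holds
only approximately; (ii) with single-KO-derived initial conditions the
initial state is already within the fitted models' calibration error
(≈ 5 % of expression at 20 genes), so the model blend does not reliably
improve on that particular baseline — the improvement is demonstrated
against the wild-type baseline, and the single-KO initial conditions
themselves cut the error several-fold.

## Numerical conventions

* Ranked lists: descending score, ties by (regulator index, target
  index); rankings are therefore deterministic and invariant to monotone
  score transforms.
* AUPR: step-wise (rectangular) area, precision × recall-increment,
  no interpolation; unlisted edges are appended with score 0 in the same
  deterministic order before scoring.
* Regulator bins: equal-count binning of regulators by their median
  expression across the KO columns (ties by label), 7 bins by default.
* All randomness (simulator, CV folds, bootstrap) flows from explicit
  integer seeds; per-gene and per-member seeds are derived additively.
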