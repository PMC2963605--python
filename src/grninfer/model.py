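"""Model/Results front end over the inference pipelines.

:class:`GRNInference` is constructed from a dataset (time series +
steady-state blocks) and hyperparameters; :meth:`GRNInference.fit` runs
one of the four pipelines and returns a :class:`GRNResults` carrying the
confidence matrix, the fitted dynamical model (where the pipeline
produces one), per-gene explanatory powers and a ``summary()`` table.

    >>> data = simulate_dream4_dataset(generate_topology(20, seed=1))
    >>> res = GRNInference(data).fit("mcz")
    >>> res.aupr(data.gold)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import (
    ConfidenceMatrix,
    DynamicalModel,
    GoldStandard,
    RankedEdgeList,
)
from .design import DEFAULT_TAU_HALF, ResponseDesign, build_response_design
from .doubleko import DoubleKOPrediction, initial_conditions, predict_double_ko
from .ensemble import (
    ensemble_medians,
    pipeline2,
    pipeline3,
    run_resampling_pipeline,
)
from .inferelator import (
    dynamical_model_from_fits,
    fit_all_genes,
    inferelator_confidences,
    select_candidates,
)
from .io import ranked_edges_from_confidence
from .mcz import corrected_wildtype, mcz_filter_mask, mcz_scores
from .metrics import aupr as _aupr
from .metrics import relative_ranks as _relative_ranks
from .simulate import Dream4Dataset
from .tlclr import mi_matrices, tlclr_scores

__all__ = ["GRNInference", "GRNResults", "PIPELINES"]

PIPELINES = ("mcz", "tlclr", "tlclr-inferelator", "tlclr-inferelator+mcz", "resampling+mcz")


@dataclass
class GRNResults:
    """Results of one pipeline run."""

    pipeline: str
    gene_ids: list[str]
    confidence: ConfidenceMatrix
    dynamical_model: DynamicalModel | None
    model: "GRNInference"
    n_resamples: int | None = None
    seed: int | None = None
    ensemble: object | None = None

    def ranked_edges(self, max_edges: int | None = None) -> RankedEdgeList:
        return ranked_edges_from_confidence(self.confidence, max_edges)

    def aupr(self, gold: GoldStandard | None = None) -> float:
        gold = gold or self.model.gold
        if gold is None:
            raise ValueError("no gold standard available")
        return _aupr(self.ranked_edges(), gold)

    def relative_ranks(self, gold: GoldStandard | None = None):
        gold = gold or self.model.gold
        if gold is None:
            raise ValueError("no gold standard available")
        return _relative_ranks(self.ranked_edges(), gold)

    def predict_double_ko(
        self,
        pairs: Sequence[tuple[str, str]],
        init: str = "single_ko_weighted",
        fixed_point_iterations: int = 0,
        wildtype_vector: np.ndarray | None = None,
    ) -> list[DoubleKOPrediction]:
        """Steady-state predictions for a list of double-KO gene pairs.

        For ``init="wildtype"`` the default initial condition is the
        released wild-type observation (the last column of the WT block);
        pass ``wildtype_vector`` to use e.g. the median-corrected estimate
        instead.
        """
        if self.dynamical_model is None:
            raise ValueError(f"pipeline {self.pipeline!r} fits no dynamical model")
        m = self.model
        if wildtype_vector is None:
            wildtype_vector = m.data.wt.values[:, -1]
        preds = []
        for pair in pairs:
            x0 = initial_conditions(
                m.data.ko,
                m.data.komap,
                pair,
                mode=init,
                Z_mcz=m.Z_mcz,
                wildtype=wildtype_vector,
            )
            preds.append(
                predict_double_ko(
                    self.dynamical_model,
                    x0,
                    pair,
                    fixed_point_iterations=fixed_point_iterations,
                )
            )
        return preds

    def summary(self, top: int = 10) -> str:
        """Plain-text summary: run parameters, top edges, model diagnostics."""
        lines = []
        n = len(self.gene_ids)
        lines.append(f"GRN inference results — pipeline: {self.pipeline}")
        lines.append(f"genes: {n}   possible edges: {n * (n - 1)}")
        if self.n_resamples:
            lines.append(f"resamples: {self.n_resamples} (seed {self.seed})")
        if self.model.gold is not None:
            lines.append(f"AUPR vs gold standard: {self.aupr():.4f}")
        lines.append("")
        lines.append(f"top {top} edges (regulator -> target, confidence):")
        for reg, tgt, score in list(self.ranked_edges())[:top]:
            lines.append(f"  {reg:>6} -> {tgt:<6} {score:.4f}")
        dm = self.dynamical_model
        if dm is not None:
            nz = int(np.count_nonzero(dm.beta))
            lines.append("")
            lines.append(
                f"dynamical model: {nz} nonzero coefficients "
                f"({nz / max(1, n):.2f} per gene), alpha = {dm.alpha:.5f}"
            )
            lines.append(
                "explanatory power h: "
                f"median {np.median(dm.h):.3f}, "
                f"IQR [{np.percentile(dm.h, 25):.3f}, {np.percentile(dm.h, 75):.3f}]"
            )
        return "\n".join(lines)


class GRNInference:
    """Network-inference model over one DREAM4-style dataset.

    Parameters
    ----------
    data : Dream4Dataset
        Time series, WT/KO/KD blocks, knock-out map and (optionally) gold
        standard, as produced by :func:`grninfer.simulate.simulate_dream4_dataset`
        or assembled from files.
    tau_half : mRNA half-life in the data's time units; the common
        degradation rate is alpha = ln2 / tau_half.
    n_bins : quantile bins for the MI estimator.
    n_candidates : K, regulators considered per target in the lasso stage.
    mcz_filter_percentile : MCZ lower-tail percentile removed before
        combination (0 disables the filter).
    """

    def __init__(
        self,
        data: Dream4Dataset,
        tau_half: float = DEFAULT_TAU_HALF,
        lags: Sequence[int] = (1, 2),
        n_bins: int = 10,
        n_candidates: int = 10,
        mcz_filter_percentile: float = 20.0,
        cv_folds: int = 10,
        s_grid=None,
        exclude_self_ko: bool = False,
        alpha_convention: str = "half_life",
    ) -> None:
        self.data = data
        self.tau_half = tau_half
        self.lags = tuple(lags)
        self.n_bins = n_bins
        self.n_candidates = n_candidates
        self.mcz_filter_percentile = mcz_filter_percentile
        self.cv_folds = cv_folds
        self.s_grid = s_grid
        self.gold = data.gold
        self.gene_ids = list(data.gene_ids)

        self.wildtype_estimate = corrected_wildtype(
            data.wt, data.ko, data.komap, exclude_self_ko=exclude_self_ko
        )
        self.Z_mcz = mcz_scores(data.ko, data.komap, self.wildtype_estimate)
        self.mcz_mask = (
            mcz_filter_mask(self.Z_mcz, mcz_filter_percentile)
            if mcz_filter_percentile > 0
            else None
        )
        self.design: ResponseDesign = build_response_design(
            data.ts,
            [data.ko, data.kd, data.wt],
            tau_half=tau_half,
            lags=self.lags,
            alpha_convention=alpha_convention,
        )

    # -- pipeline runners ---------------------------------------------------

    def _results(self, pipeline, Z, dm=None, n_resamples=None, seed=None) -> GRNResults:
        return GRNResults(
            pipeline=pipeline,
            gene_ids=list(self.gene_ids),
            confidence=Z,
            dynamical_model=dm,
            model=self,
            n_resamples=n_resamples,
            seed=seed,
        )

    def fit(self, pipeline: str = "resampling+mcz", n_resamples: int = 200, seed: int = 0) -> GRNResults:
        """Run one inference pipeline and return its results.

        ``pipeline`` is one of ``mcz`` (knock-out z-scores only), ``tlclr``
        (MI + background correction), ``tlclr-inferelator`` (pipeline 2),
        ``tlclr-inferelator+mcz`` (pipeline 3) or ``resampling+mcz``
        (pipeline 4; ``n_resamples`` bootstrap members).
        """
        if pipeline not in PIPELINES:
            raise ValueError(f"unknown pipeline {pipeline!r}; choose from {PIPELINES}")
        if pipeline == "mcz":
            return self._results("mcz", self.Z_mcz)
        if pipeline == "tlclr":
            mi = mi_matrices(self.design, n_bins=self.n_bins)
            Z_tl = tlclr_scores(mi.M_dyn, mi.M_stat, self.gene_ids)
            return self._results("tlclr", Z_tl)
        if pipeline in ("tlclr-inferelator", "tlclr-inferelator+mcz"):
            mi = mi_matrices(self.design, n_bins=self.n_bins)
            Z_tl = tlclr_scores(mi.M_dyn, mi.M_stat, self.gene_ids)
            cand = select_candidates(Z_tl, self.mcz_mask, self.n_candidates)
            fits, mean, sd = fit_all_genes(
                self.design, cand, k_folds=self.cv_folds, s_grid=self.s_grid, seed=seed
            )
            Z_inf = inferelator_confidences(fits, self.gene_ids)
            Z_p2 = pipeline2(Z_tl, Z_inf)
            dm = dynamical_model_from_fits(
                fits, self.gene_ids, self.design.alpha, mean, sd
            )
            if pipeline == "tlclr-inferelator":
                return self._results("tlclr-inferelator", Z_p2, dm, seed=seed)
            Z_p3 = pipeline3(Z_p2, self.Z_mcz)
            return self._results("tlclr-inferelator+mcz", Z_p3, dm, seed=seed)
        # pipeline 4
        ensemble = run_resampling_pipeline(
            self.design,
            self.Z_mcz,
            mcz_mask=self.mcz_mask,
            M=n_resamples,
            K=self.n_candidates,
            n_bins=self.n_bins,
            k_folds=self.cv_folds,
            s_grid=self.s_grid,
            seed=seed,
        )
        Z_p4, dm = ensemble_medians(ensemble)
        res = self._results(
            "resampling+mcz", Z_p4, dm, n_resamples=n_resamples, seed=seed
        )
        res.ensemble = ensemble
        return res
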