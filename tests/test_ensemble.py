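"""Rank transplant, bootstrap, and ensemble median aggregation."""

import numpy as np
import pytest
from scipy.stats import rankdata

from grninfer.datamodel import ConfidenceMatrix, DynamicalModel
from grninfer.ensemble import (
    NetworkEnsemble,
    bootstrap_columns,
    ensemble_medians,
    pipeline3,
    rank_transplant_combine,
    run_resampling_pipeline,
)
from grninfer.io import ranked_edges_from_confidence


def _Z(vals):
    genes = [f"G{i+1}" for i in range(len(vals))]
    return ConfidenceMatrix(genes, np.asarray(vals, dtype=float))


class TestRankTransplant:
    def test_identical_rankings_double_the_reference(self):
        A = _Z([[0, 3, 2], [1, 0, 5], [4, 6, 0]])
        combined = rank_transplant_combine(A, A)
        np.testing.assert_allclose(combined.values, 2 * A.values)

    def test_single_nonzero_entry_receives_reference_maximum(self):
        A = _Z([[0, 3, 2], [1, 0, 5], [4, 6, 0]])
        B = _Z([[0, 0, 0], [0.5, 0, 0], [0, 0, 0]])
        combined = rank_transplant_combine(A, B)
        # B's only nonzero entry gets A's max (6); combined = A + B'
        assert combined.values[1, 0] == A.values[1, 0] + 6
        # all other entries are pure A
        mask = np.ones((3, 3), dtype=bool)
        mask[1, 0] = False
        np.testing.assert_array_equal(combined.values[mask], A.values[mask])

    def test_hand_traced_three_by_three(self):
        # A off-diagonal sorted desc: 9, 7, 4, 3, 2, 1
        A = _Z([[0, 9, 4], [3, 0, 1], [7, 2, 0]])
        # B nonzeros: (0,2)=5 > (1,0)=2 > (2,1)=0.5
        B = _Z([[0, 0, 5], [2, 0, 0], [0, 0.5, 0]])
        combined = rank_transplant_combine(A, B)
        # transplant: (0,2)<-9, (1,0)<-7, (2,1)<-4; combined = A + B'
        expected = A.values + np.array(
            [[0, 0, 9.0], [7.0, 0, 0], [0, 4.0, 0]]
        )
        np.testing.assert_array_equal(combined.values, expected)

    def test_preserves_reference_order_for_matching_rankings(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.1, 1, size=(5, 5))
        A = _Z(vals)
        B = _Z(vals ** 3)  # same ranking, different scale
        combined = rank_transplant_combine(A, B)
        ours = [(r, t) for r, t, _ in ranked_edges_from_confidence(combined)]
        ref = [(r, t) for r, t, _ in ranked_edges_from_confidence(A)]
        assert ours == ref


class TestPipeline3:
    def test_empty_p2_reduces_to_mcz(self):
        Z_mcz = _Z([[0, 2, 1], [3, 0, 4], [5, 6, 0]])
        Z_p2 = _Z(np.zeros((3, 3)))
        combined = pipeline3(Z_p2, Z_mcz)
        np.testing.assert_array_equal(combined.values, Z_mcz.values)

    def test_zero_mcz_reference_yields_zero_matrix(self):
        Z_mcz = _Z(np.zeros((3, 3)))
        Z_p2 = _Z([[0, 2, 1], [3, 0, 4], [5, 6, 0]])
        combined = pipeline3(Z_p2, Z_mcz)
        np.testing.assert_array_equal(combined.values, 0.0)


class TestBootstrap:
    def test_deterministic_given_seed(self, small_model):
        a = bootstrap_columns(small_model.design, seed=3)
        b = bootstrap_columns(small_model.design, seed=3)
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.X, b.X)

    def test_distinct_column_fraction_near_632(self, small_model):
        rd = small_model.design
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, rd.n_obs, size=rd.n_obs)
            fractions.append(len(set(idx.tolist())) / rd.n_obs)
        assert np.mean(fractions) == pytest.approx(1 - np.exp(-1), abs=0.02)

    def test_pairing_preserved(self, small_model):
        rd = small_model.design
        resampled = bootstrap_columns(rd, seed=5)
        # every resampled (Y, X) column pair must exist as a pair in rd
        original = {tuple(np.concatenate([rd.Y[:, k], rd.X[:, k]])) for k in range(rd.n_obs)}
        for k in range(resampled.n_obs):
            col = tuple(np.concatenate([resampled.Y[:, k], resampled.X[:, k]]))
            assert col in original


class TestResamplingPipeline:
    def test_identity_member_equals_plain_pipeline3(self, small_model):
        from grninfer.ensemble import _single_pipeline3

        gm = small_model
        ens = run_resampling_pipeline(
            gm.design, gm.Z_mcz, gm.mcz_mask, M=1, K=gm.n_candidates,
            seed=9, identity_first=True,
        )
        Z_direct, model_direct = _single_pipeline3(
            gm.design, gm.Z_mcz, gm.mcz_mask, gm.n_candidates, 10, 10, None, 9
        )
        Z_member, model_member = ens.members[0]
        np.testing.assert_array_equal(Z_member.values, Z_direct.values)
        np.testing.assert_array_equal(model_member.beta, model_direct.beta)

    def test_byte_identical_across_runs(self, small_model):
        gm = small_model
        kw = dict(mcz_mask=gm.mcz_mask, M=2, K=gm.n_candidates, seed=4)
        e1 = run_resampling_pipeline(gm.design, gm.Z_mcz, **kw)
        e2 = run_resampling_pipeline(gm.design, gm.Z_mcz, **kw)
        for (Za, ma), (Zb, mb) in zip(e1.members, e2.members):
            np.testing.assert_array_equal(Za.values, Zb.values)
            np.testing.assert_array_equal(ma.beta, mb.beta)


class TestEnsembleMedians:
    def _member(self, Z_vals, beta, genes):
        n = len(genes)
        model = DynamicalModel(
            gene_ids=genes, beta=beta, bias=np.zeros(n), h=np.full(n, 0.5),
            alpha=0.0139, regressor_mean=np.zeros(n), regressor_sd=np.ones(n),
        )
        return (_Z(Z_vals), model)

    def test_identical_members_reproduce_member_ordering(self):
        genes = ["G1", "G2", "G3"]
        Z_vals = [[0, 5, 1], [2, 0, 6], [3, 4, 0]]
        beta = np.array([[0, 0.5, 0], [0, 0, -0.2], [0.1, 0, 0]])
        E = NetworkEnsemble(genes, [self._member(Z_vals, beta, genes)] * 3, seed=0)
        Z_med, model_med = ensemble_medians(E)
        ours = [(r, t) for r, t, _ in ranked_edges_from_confidence(Z_med)]
        ref = [(r, t) for r, t, _ in ranked_edges_from_confidence(_Z(Z_vals))]
        assert ours == ref
        np.testing.assert_array_equal(model_med.beta, beta)

    def test_median_beta_respects_sparsity(self):
        genes = ["G1", "G2"]
        betas = [np.array([[0, b], [0, 0]]) for b in (0.0, 0.0, 0.6)]
        members = [self._member(np.zeros((2, 2)), b, genes) for b in betas]
        _, model_med = ensemble_medians(NetworkEnsemble(genes, members, 0))
        assert model_med.beta[0, 1] == 0.0

    def test_median_rank_odd_ensemble(self):
        # an edge ranked 1, 5, 9 across three members has median rank 5
        genes = [f"G{i+1}" for i in range(4)]  # 12 possible edges
        rng = np.random.default_rng(1)
        members = []
        target_ranks = [1, 5, 9]
        for want in target_ranks:
            # build a matrix where edge (0,1) has the desired rank
            vals = np.zeros((4, 4))
            offdiag = [(i, j) for i in range(4) for j in range(4) if i != j]
            scores = -rankdata(rng.uniform(size=len(offdiag)))  # distinct
            for (i, j), s in zip(offdiag, scores):
                vals[i, j] = s
            # shift edge (0,1) so its rank is exactly `want`
            order = sorted(offdiag, key=lambda e: -vals[e])
            current = order.index((0, 1)) + 1
            swap = order[want - 1]
            vals[(0, 1)], vals[swap] = vals[swap], vals[(0, 1)]
            vals = vals - vals.min() + 1.0
            np.fill_diagonal(vals, 0)
            members.append(self._member(vals, np.zeros((4, 4)), genes))
        Z_med, _ = ensemble_medians(NetworkEnsemble(genes, members, 0))
        P = 12
        # median rank 5 -> confidence P + 1 - 5 = 8
        assert Z_med.values[0, 1] == pytest.approx(P + 1 - 5)

    def test_ordering_invariant_under_monotone_member_transforms(self):
        genes = [f"G{i+1}" for i in range(4)]
        rng = np.random.default_rng(2)
        base = [rng.uniform(0.1, 1, size=(4, 4)) for _ in range(3)]
        members_raw = [self._member(v, np.zeros((4, 4)), genes) for v in base]
        members_tr = [
            self._member(np.exp(3 * v), np.zeros((4, 4)), genes) for v in base
        ]
        Z_raw, _ = ensemble_medians(NetworkEnsemble(genes, members_raw, 0))
        Z_tr, _ = ensemble_medians(NetworkEnsemble(genes, members_tr, 0))
        raw = [(r, t) for r, t, _ in ranked_edges_from_confidence(Z_raw)]
        tr = [(r, t) for r, t, _ in ranked_edges_from_confidence(Z_tr)]
        assert raw == tr
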