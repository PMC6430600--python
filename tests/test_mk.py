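import numpy as np
import pytest

from phyloarb import (MkModel, Tree, fit_mk, marginal_asr, mk_loglik,
                      simulate_mk_trait, simulate_yule, transition_matrix)
from phyloarb.mk import fit_er_rates
from oracles import enumeration_mk, random_binary_tree, transition_matrix_expm


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        P = transition_matrix(MkModel("ER", (2.0,)), 0.0)
        assert np.allclose(P, np.eye(2))

    def test_long_time_reaches_stationary(self):
        P = transition_matrix(MkModel("ER", (1.0,)), 1e6)
        assert np.allclose(P, 0.5)
        P = transition_matrix(MkModel("ARD", (3.0, 1.0)), 1e6)
        assert np.allclose(P, [[0.25, 0.75], [0.25, 0.75]])

    @pytest.mark.parametrize("q,t", [(1.0, 0.5), (0.3, 2.0), (5.0, 0.1)])
    def test_er_matches_matrix_exponential(self, q, t):
        P = transition_matrix(MkModel("ER", (q,)), t)
        assert np.allclose(P, transition_matrix_expm(q, t), atol=1e-12)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_er_hand_value(self):
        P = transition_matrix(MkModel("ER", (1.0,)), 0.5)
        assert P[0, 0] == pytest.approx(0.683940, abs=1e-6)
        assert P[0, 1] == pytest.approx(0.316060, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(MkModel("ER", (1.0,)), -0.1)


class TestLogLik:
    def test_two_leaf_hand_value(self, cherry):
        # enumerate both root states: 0.5 * (P00 P01 + P01 P00) with t=0.5
        logl = mk_loglik(cherry, {"A": 0, "B": 1}, MkModel("ER", (1.0,)))
        assert logl == pytest.approx(np.log(0.216166), abs=1e-4)

    def test_matches_enumeration_on_random_trees(self, rng):
        for _ in range(15):
            t = random_binary_tree(int(rng.integers(3, 7)), rng)
            tips = {lb: int(rng.random() < 0.5) for lb in t.leaf_labels()}
            model = MkModel("ER", (float(rng.uniform(0.05, 2.0)),))
            _, logl = enumeration_mk(t, tips, model)
            assert mk_loglik(t, tips, model) == pytest.approx(logl, abs=1e-10)

    def test_saturated_branches_give_independent_halves(self):
        t = Tree.from_newick("(A:1e7,B:1e7);")
        logl = mk_loglik(t, {"A": 0, "B": 1}, MkModel("ER", (1.0,)))
        assert logl == pytest.approx(np.log(0.25), abs=1e-6)

    def test_tiny_rate_identical_tips_approaches_prior(self, cherry):
        logl = mk_loglik(cherry, {"A": 1, "B": 1}, MkModel("ER", (1e-9,)))
        assert logl == pytest.approx(np.log(0.5), abs=1e-6)

    def test_er_loglik_invariant_under_rerooting(self, rng):
        # time-reversibility with a flat prior
        for _ in range(10):
            t = random_binary_tree(int(rng.integers(4, 9)), rng)
            tips = {lb: int(rng.random() < 0.5) for lb in t.leaf_labels()}
            model = MkModel("ER", (0.7,))
            base = mk_loglik(t, tips, model)
            for node in t.internal_nodes():
                if node is t.root:
                    continue
                assert mk_loglik(t.reroot_at(node.id), tips, model) == \
                    pytest.approx(base, abs=1e-10)

    def test_strict_missing_policy_raises(self, quartet):
        with pytest.raises(ValueError):
            mk_loglik(quartet, {"A": 0, "B": 1, "C": 0}, MkModel(), missing="strict")

    def test_polytomy_rejected(self):
        # a non-root polytomy is a genuinely unresolved node
        t = Tree.from_newick("((A:1,B:1,C:1):1,D:1);")
        with pytest.raises(ValueError):
            mk_loglik(t, {"A": 0, "B": 1, "C": 0, "D": 1}, MkModel())


class TestFit:
    def test_fitted_rate_beats_dense_grid(self, rng):
        t = random_binary_tree(8, rng)
        tips = {lb: int(rng.random() < 0.5) for lb in t.leaf_labels()}
        fit = fit_mk(t, tips)
        grid = np.logspace(-6, 3, 50)
        best_grid = max(mk_loglik(t, tips, MkModel("ER", (float(q),))) for q in grid)
        assert fit.log_likelihood >= best_grid - 1e-6

    def test_identical_tips_hit_lower_bound(self, quartet):
        fit = fit_mk(quartet, {lb: 1 for lb in quartet.leaf_labels()})
        assert fit.at_bound
        assert fit.model.rates[0] == pytest.approx(1e-6, rel=0.1)
        assert fit.log_likelihood == pytest.approx(np.log(0.5), abs=1e-4)

    def test_two_leaf_conflicting_tips_plateau(self, cherry):
        # with one tip each state the likelihood plateaus at
        # sum_s pi_s * 1/2 * 1/2 = 1/4 as q grows
        fit = fit_mk(cherry, {"A": 0, "B": 1})
        assert fit.log_likelihood == pytest.approx(np.log(0.25), abs=1e-4)

    def test_missing_tips_pruned(self, quartet):
        fit = fit_mk(quartet, {"A": 0, "B": 1, "C": 0, "D": None})
        assert set(fit.tree.leaf_labels()) == {"A", "B", "C"}

    def test_ard_recovers_asymmetry_direction(self):
        t = simulate_yule(60, seed=11)
        rng2 = np.random.default_rng(42)
        tips = {lb: int(rng2.random() < 0.85) for lb in t.leaf_labels()}
        fit = fit_mk(t, tips, model_class="ARD", root_prior="stationary")
        q01, q10 = fit.model.rates
        assert q01 > q10  # 0 -> 1 flow must dominate to explain mostly-1 tips

    def test_batch_fit_agrees_with_single(self, rng):
        t = random_binary_tree(10, rng)
        import pandas as pd
        cols = {}
        for j in range(4):
            cols[f"tr{j}"] = {lb: int(rng.random() < 0.5) for lb in t.leaf_labels()}
        frame = pd.DataFrame(cols).loc[t.leaf_labels()]
        batch = fit_er_rates(t, frame)
        for j in range(4):
            single = fit_mk(t, frame[f"tr{j}"].to_dict())
            assert batch.loc[f"tr{j}", "log_likelihood"] == pytest.approx(
                single.log_likelihood, abs=1e-8)


class TestMarginalAsr:
    def test_symmetric_cherry_root_is_half(self, cherry):
        fit = fit_mk(cherry, {"A": 0, "B": 1})
        asr = marginal_asr(cherry, {"A": 0, "B": 1}, fit)
        assert np.allclose(asr.root_posterior, [0.5, 0.5])

    def test_matches_enumeration_on_random_trees(self, rng):
        """Re-rooting marginals == exhaustive marginalisation, <=6 leaves."""
        for _ in range(25):
            t = random_binary_tree(int(rng.integers(4, 7)), rng)
            tips = {lb: int(rng.random() < 0.5) for lb in t.leaf_labels()}
            if len(set(tips.values())) < 2:
                first = t.leaf_labels()[0]
                tips[first] = 1 - tips[first]
            fit = fit_mk(t, tips)
            asr = marginal_asr(t, tips, fit)
            post, logl = enumeration_mk(t, tips, fit.model)
            assert fit.log_likelihood == pytest.approx(logl, abs=1e-8)
            for nid, expected in post.items():
                assert np.allclose(asr[nid], expected, atol=1e-8)

    def test_posteriors_sum_to_one(self, rng):
        t = random_binary_tree(12, rng)
        tips = {lb: int(rng.random() < 0.5) for lb in t.leaf_labels()}
        asr = marginal_asr(t, tips)
        for nid in asr:
            assert abs(asr[nid].sum() - 1.0) < 1e-10

    def test_uniform_presence_pulls_all_nodes_up(self, rng):
        t = random_binary_tree(8, rng)
        tips = {lb: 1 for lb in t.leaf_labels()}
        tips[t.leaf_labels()[0]] = 0  # one absence so the rate is estimable
        asr = marginal_asr(t, tips, fit_mk(t, tips))
        assert sum(asr[nid][1] > 0.5 for nid in asr) >= len(asr.posteriors) - 1

    def test_mismatched_fit_rejected(self, quartet, cherry):
        fit = fit_mk(cherry, {"A": 0, "B": 1})
        with pytest.raises(ValueError):
            marginal_asr(quartet, {"A": 0, "B": 1, "C": 0, "D": 1}, fit)

    def test_output_frame_shape(self, quartet):
        tips = {"A": 0, "B": 0, "C": 1, "D": 1}
        frame = marginal_asr(quartet, tips).to_frame()
        assert len(frame) == 3  # three internal nodes on a rooted quartet
        assert np.allclose(frame[["p_state0", "p_state1"]].sum(axis=1), 1.0)
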