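import numpy as np
import pytest

from phyloarb import (FixtureSpec, Tree, distort_branch_lengths, gc_content,
                      make_study_fixture, simulate_bm_trait, simulate_mk_trait,
                      simulate_yule)


class TestYule:
    def test_minimal_cherry(self):
        t = simulate_yule(2, seed=0)
        assert t.n_leaves == 2 and t.is_binary()

    def test_internal_node_count(self):
        t = simulate_yule(20, seed=3)
        assert len(t.internal_nodes()) == 19

    def test_determinism(self):
        assert simulate_yule(15, seed=7).to_newick() == simulate_yule(15, seed=7).to_newick()

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            simulate_yule(1)


class TestDistort:
    def test_unit_factors_identity(self, study_bundle):
        t = study_bundle.tree_uniform
        g4 = frozenset(study_bundle.groups["group4"])
        out = distort_branch_lengths(t, {g4: 1.0})
        assert out.to_newick() == t.to_newick()

    def test_clade_scaling_exact(self, study_bundle):
        t = study_bundle.tree_uniform
        g4 = study_bundle.groups["group4"]

        def subtree_length(tree):
            top = tree.mrca(g4)
            total, stack = 0.0, list(top.children)
            while stack:
                nd = stack.pop()
                total += nd.length or 0.0
                stack.extend(nd.children)
            return total

        out = distort_branch_lengths(t, {frozenset(g4): 0.02})
        assert subtree_length(out) == pytest.approx(0.02 * subtree_length(t))

    def test_other_clades_untouched(self, study_bundle):
        t = study_bundle.tree_uniform
        out = distort_branch_lengths(t, {frozenset(study_bundle.groups["group4"]): 0.02})
        before = t.leaf_distances()
        after = out.leaf_distances()
        g1 = study_bundle.groups["group1"]
        for i, a in enumerate(g1):
            for b in g1[i + 1:]:
                key = (a, b) if a < b else (b, a)
                assert after[key] == pytest.approx(before[key])

    def test_non_clade_rejected(self, study_bundle):
        t = study_bundle.tree_uniform
        not_a_clade = study_bundle.groups["group1"][:1] + study_bundle.groups["group4"][:1]
        with pytest.raises(ValueError):
            distort_branch_lengths(t, {frozenset(not_a_clade): 2.0})


class TestTraitSimulators:
    def test_zero_rate_keeps_root_state(self, study_bundle):
        t = study_bundle.tree_uniform
        assert set(simulate_mk_trait(t, 0.0, root_state=1, seed=4).values()) == {1}
        vals = simulate_bm_trait(t, 0.0, root_value=2.0, seed=4)
        assert set(vals.values()) == {2.0}

    def test_single_branch_flip_frequency_matches_closed_form(self):
        t = Tree.from_newick("(A:0.8,B:0.8);")
        q, reps = 0.6, 10000
        rng = np.random.default_rng(77)
        flips = sum(simulate_mk_trait(t, q, 0, seed=rng)["A"] for _ in range(reps))
        p = 0.5 * (1 - np.exp(-2 * q * 0.8))
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(flips / reps - p) < 3 * se

    def test_high_rate_tips_near_bernoulli_half(self):
        t = Tree.from_newick("(A:5,B:5);")
        rng = np.random.default_rng(7)
        ones = sum(simulate_mk_trait(t, 50.0, 0, seed=rng)["A"] for _ in range(1000))
        assert abs(ones / 1000 - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_bm_tip_variance_on_star(self):
        t = Tree.from_newick("(A:2,B:2,C:2,D:2);")
        rng = np.random.default_rng(11)
        draws = np.array([list(simulate_bm_trait(t, 1.5, 0.0, seed=rng).values())
                          for _ in range(2000)])
        target = 1.5 * 2.0
        se = target * np.sqrt(2 / (draws.size - 1))
        assert abs(draws.var() - target) < 3 * se

    def test_bm_sister_covariance(self):
        t = Tree.from_newick("((A:1,B:1):2,C:3);")
        rng = np.random.default_rng(13)
        reps = [simulate_bm_trait(t, 1.0, 0.0, seed=rng) for _ in range(3000)]
        draws = np.array([[r["A"], r["B"]] for r in reps])
        cov = np.cov(draws.T)[0, 1]
        # shared path to root = 2; sampling s.e. of covariance ~ sqrt((v11*v22+c^2)/n)
        se = np.sqrt((3 * 3 + 4) / 3000)
        assert abs(cov - 2.0) < 3 * se


class TestStudyFixture:
    def test_shape_contract(self, study_bundle):
        assert study_bundle.tree_uniform.n_leaves == 55
        assert study_bundle.traits.data.shape == (55, 25)
        assert len(study_bundle.traits.discrete) == 13
        assert len(study_bundle.traits.continuous) == 12
        assert len(study_bundle.fragments) == 6
        assert study_bundle.tree_uniform.is_binary()
        assert (set(study_bundle.tree_uniform.leaf_labels())
                == set(study_bundle.tree_heterogeneous.leaf_labels()))

    def test_rival_trees_same_topology(self, study_bundle):
        assert (study_bundle.tree_uniform.split_set()
                == study_bundle.tree_heterogeneous.split_set())

    def test_groups_are_clades(self, study_bundle):
        clades = study_bundle.tree_uniform.clades().values()
        for g in ("group1", "group2", "group3", "group4"):
            assert frozenset(study_bundle.groups[g]) in clades

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        spec = FixtureSpec(seed=5, group_sizes=(2, 3, 4, 8), n_discrete=4,
                           n_continuous=3)
        d1, d2 = tmp_path / "one", tmp_path / "two"
        p1 = make_study_fixture(spec).write(d1)
        p2 = make_study_fixture(spec).write(d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_gc_targets_realized(self, study_bundle):
        lo_taxon = study_bundle.groups["group4"][0]
        hi_taxon = study_bundle.groups["group2"][0]
        def pooled(taxon):
            return gc_content([a.records[taxon] for a in study_bundle.fragments
                               if taxon in a.records])
        assert pooled(lo_taxon) == pytest.approx(0.27, abs=0.02)
        assert pooled(hi_taxon) == pytest.approx(0.61, abs=0.02)

    def test_discrete_traits_binarizable(self, study_bundle):
        for tr in study_bundle.traits.discrete:
            col = study_bundle.traits.binary(tr).dropna()
            assert set(col.unique()) <= {0, 1}
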