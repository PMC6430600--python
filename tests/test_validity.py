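import math

import numpy as np
import pandas as pd
import pytest

from phyloarb import (TraitTable, Tree, binarize, compare_continuous,
                      compare_discrete, load_published_loglik_table,
                      load_published_variance_ratios, simulate_bm_trait,
                      simulate_mk_trait, summarize, tree_validity, variance_ratio)
from phyloarb.brownian import ancestral_estimates


class TestBinarize:
    def test_presence_absence_strings(self):
        col = pd.Series({"t1": "yes", "t2": "no", "t3": "yes"}, name="habit")
        out = binarize(col, {"yes": 1, "no": 0})
        assert out.to_dict() == {"t1": 1, "t2": 0, "t3": 1}

    def test_identity_on_binary(self):
        col = pd.Series({"t1": 1, "t2": 0}, name="x")
        assert binarize(col, None).to_dict() == {"t1": 1, "t2": 0}

    def test_missing_preserved(self):
        col = pd.Series({"t1": "yes", "t2": None}, name="x")
        out = binarize(col, {"yes": 1, "no": 0})
        assert out["t1"] == 1 and math.isnan(out["t2"])

    def test_uncovered_value_errors_naming_it(self):
        col = pd.Series({"t1": "sometimes"}, name="x")
        with pytest.raises(ValueError, match="sometimes"):
            binarize(col, {"yes": 1, "no": 0})


class TestCompare:
    def test_identical_trees_tie(self, study_bundle):
        tree = study_bundle.tree_uniform
        states = simulate_mk_trait(tree, 0.4, seed=5)
        result = compare_discrete(tree, tree.copy(), states, trait="x")
        assert result.favoured == "tie"
        assert result.logl_a == pytest.approx(result.logl_b, abs=1e-6)

    def test_identical_trees_unit_ratio(self, study_bundle):
        tree = study_bundle.tree_uniform
        x = simulate_bm_trait(tree, 1.0, seed=6)
        result = compare_continuous(tree, tree.copy(), x, trait="y")
        assert result.ratio == pytest.approx(1.0, abs=1e-9)

    def test_variance_ratio_linearity(self, study_bundle):
        tree = study_bundle.tree_uniform
        x = simulate_bm_trait(tree, 1.0, seed=7)
        a = ancestral_estimates(tree, x)
        b = ancestral_estimates(tree, x)
        base = variance_ratio(a, b)
        b.variances = {k: 2 * v for k, v in b.variances.items()}
        assert variance_ratio(a, b) == pytest.approx(base / 2)

    def test_published_stalk_support_direction(self):
        table = load_published_loglik_table().set_index("trait")
        row = table.loc["Stalk support"]
        assert summarize([(row.logl_aapprs, row.logl_ssu_rdna)]).favoured_a == 1

    def test_generating_tree_wins_majority(self, study_bundle):
        """Traits simulated on tree A are favoured on tree A more often
        than not (25 replicate binary traits)."""
        a, b = study_bundle.tree_uniform, study_bundle.tree_heterogeneous
        rng = np.random.default_rng(123)
        wins = 0
        for _ in range(25):
            states = simulate_mk_trait(a, 0.5, root_state=int(rng.random() < 0.5), seed=rng)
            if len(set(states.values())) < 2:
                continue
            res = compare_discrete(a, b, states, trait="sim")
            wins += res.favoured == "A"
        assert wins > 12

    def test_continuous_generating_tree_tighter(self, study_bundle):
        a, b = study_bundle.tree_uniform, study_bundle.tree_heterogeneous
        rng = np.random.default_rng(321)
        ratios = [compare_continuous(a, b, simulate_bm_trait(a, 1.0, seed=rng)).ratio
                  for _ in range(15)]
        assert np.mean(ratios) < 1.0


class TestSummarize:
    def test_single_pair(self):
        s = summarize([(-1.0, -2.0)])
        assert (s.favoured_a, s.favoured_b) == (1, 0)
        assert s.mean_advantage_a == pytest.approx(1.0)
        assert math.isnan(s.mean_advantage_b)

    def test_ties_excluded(self):
        s = summarize([(-1.0, -1.0), (-2.0, -3.0)])
        assert s.ties == 1 and s.favoured_a == 1

    def test_published_table_reproduces_reported_statistics(self):
        """The printed 13 log-likelihood pairs split 7/6 with a mean
        advantage of 3.44 for the multi-protein tree; the 12 variance
        ratios average 0.2533 ('four-fold lower')."""
        logl = load_published_loglik_table()
        ratios = load_published_variance_ratios()
        s = summarize(list(zip(logl.logl_aapprs, logl.logl_ssu_rdna)),
                      ratios.variance_ratio_aapprs_over_ssu)
        assert (s.favoured_a, s.favoured_b, s.ties) == (7, 6, 0)
        assert s.mean_advantage_a == pytest.approx(3.44, abs=0.005)
        assert s.mean_variance_ratio == pytest.approx(0.2533, abs=0.0005)
        assert 1 / s.mean_variance_ratio == pytest.approx(4.0, rel=0.02)


class TestTraitTable:
    def test_roundtrip_and_pipeline(self, small_bundle, tmp_path):
        paths = small_bundle.write(tmp_path)
        table = TraitTable.from_files(paths["traits"], paths["rules"])
        assert table.discrete == small_bundle.traits.discrete
        assert table.continuous == small_bundle.traits.continuous
        report = tree_validity(small_bundle.tree_uniform,
                               small_bundle.tree_heterogeneous, table)
        frame = report.to_frame()
        assert len(frame) == len(table.discrete) + len(table.continuous)
        assert set(frame.kind) == {"discrete", "continuous"}

    def test_binary_accessor_applies_rules(self, study_bundle):
        table = study_bundle.traits
        raw_rule_traits = [t for t in table.discrete if t in table.rules]
        col = table.binary(raw_rule_traits[0]).dropna()
        assert set(col.unique()) <= {0, 1}

    def test_duplicate_taxa_rejected(self):
        df = pd.DataFrame({"x": [1, 0]}, index=["a", "a"])
        with pytest.raises(ValueError):
            TraitTable(df, ["x"], [])
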