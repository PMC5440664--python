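import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, chisquare

from phaseuncouple import expression_phase as ep
from phaseuncouple import synthetic_data as syn
from phaseuncouple import traits
from phaseuncouple.phylo_io import MISSING, Phylogeny, read_newick


class TestSimulateTree:
    def test_tip_count_and_ultrametric(self):
        tree = syn.simulate_tree(50, birth=1.0, seed=1)
        assert tree.n_tips == 50
        assert np.allclose(tree.age[tree.tips], 0.0)

    def test_seed_determinism(self):
        t1 = syn.simulate_tree(30, seed=9)
        t2 = syn.simulate_tree(30, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_yule_root_age_matches_closed_form(self):
        lam, n = 1.0, 20
        ages = [syn.simulate_tree(n, birth=lam, seed=s).T for s in range(500)]
        expected = sum(1.0 / (lam * k) for k in range(2, n + 1))
        assert np.mean(ages) == pytest.approx(expected, rel=0.1)

    def test_with_extinction(self):
        tree = syn.simulate_tree(30, birth=1.0, death=0.4, seed=2)
        assert tree.n_tips == 30

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_tree(2)


class TestSimulateTraits:
    def test_bm_tip_difference_variance(self, toy_tree):
        sims = traits.simulate_bm(toy_tree, np.random.default_rng(3),
                                  sigma2=1.5, nsim=20000)
        d = sims[:, 0] - sims[:, 1]  # tips A,B diverged for 1 Myr each
        assert d.var() == pytest.approx(2 * 1.5 * 1.0, rel=0.05)

    def test_coupled_phases_share_shift_branches(self, tree64):
        spec = syn.ScenarioSpec(n_tips=64, coupling="coupled", n_shifts=4,
                                seed=0)
        tr = syn.simulate_traits(tree64, spec, seed=5)
        sb = tr["truth"]["shift_branches"]
        assert sb["adult"] == sb["tadpole"]

    def test_multi_axis_shape(self, tree64):
        spec = syn.ScenarioSpec(n_tips=64, n_axes=3, n_shifts=2, seed=0)
        tr = syn.simulate_traits(tree64, spec, seed=6)
        assert tr["adult"].shape == (64, 3)


class TestSimulateMk:
    def test_zero_rate_constant_characters(self, tree20):
        spec = syn.ScenarioSpec(n_characters=5, mk_rate=0.0,
                                missing_fraction=0.0, seed=1)
        m = syn.simulate_mk(tree20, spec)
        assert all(len(np.unique(m.states[:, j])) == 1
                   for j in range(m.n_characters))

    def test_high_rate_uniform_states(self):
        tree = syn.simulate_tree(10, seed=4)
        spec = syn.ScenarioSpec(n_characters=1000, n_states=3, mk_rate=50.0,
                                missing_fraction=0.0, ordered_fraction=0.0,
                                seed=5)
        m = syn.simulate_mk(tree, spec)
        # one tip gives iid draws across characters
        counts = np.bincount(m.states[0], minlength=3)
        assert chisquare(counts).pvalue > 0.05

    def test_missing_fraction(self, tree20):
        spec = syn.ScenarioSpec(n_characters=200, missing_fraction=0.2,
                                seed=6)
        m = syn.simulate_mk(tree20, spec)
        frac = (m.states == MISSING).mean()
        assert frac == pytest.approx(0.2, abs=0.03)

    def test_dependent_pairs_more_associated(self, tree64):
        def cramers_v(a, b):
            tab = pd.crosstab(a, b)
            if tab.shape != (2, 2):
                return np.nan
            chi2 = chi2_contingency(tab, correction=False)[0]
            return np.sqrt(chi2 / len(a))

        vd = np.nanmean([cramers_v(*syn.simulate_binary_pair(
            tree64, 0.4, 8.0, seed=s)) for s in range(20)])
        vi = np.nanmean([cramers_v(*syn.simulate_binary_pair(
            tree64, 0.4, 1.0, seed=100 + s)) for s in range(20)])
        assert vd > vi + 0.2


class TestSimulateExpression:
    def test_no_bias_low_false_positives(self):
        spec = syn.ScenarioSpec(n_genes=2000, frac_adult_biased=0.0,
                                frac_tadpole_biased=0.0, seed=2)
        res = ep.classify_phase_bias(syn.simulate_expression(spec))
        fp = (res.counts["adult-biased"] + res.counts["tadpole-biased"]) \
            / spec.n_genes
        assert fp < 0.05

    def test_planted_fraction_recovered(self):
        spec = syn.ScenarioSpec(n_genes=2000, frac_adult_biased=0.30,
                                frac_tadpole_biased=0.10, seed=1)
        res = ep.classify_phase_bias(syn.simulate_expression(spec))
        assert res.counts["adult-biased"] / spec.n_genes == pytest.approx(
            0.30, abs=0.05)

    def test_seed_determinism(self):
        spec = syn.ScenarioSpec(n_genes=100, seed=7)
        t1 = syn.simulate_expression(spec)
        t2 = syn.simulate_expression(spec)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            syn.ScenarioSpec(frac_adult_biased=0.7, frac_tadpole_biased=0.5)


class TestScenario:
    def test_generate_writes_all_files(self, tmp_path):
        spec = syn.ScenarioSpec(n_tips=16, n_characters=8, n_genes=50,
                                n_shifts=2, min_clade=2, seed=3)
        syn.generate_scenario(spec, tmp_path)
        for name in ("tree.nwk", "adult.nex", "tadpole.nex",
                     "expression.tsv", "scenario.yaml", "truth.json"):
            assert (tmp_path / name).exists()
        tree = read_newick(tmp_path / "tree.nwk")
        assert tree.n_tips == 16
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth["shift_branches"]) == {"adult", "tadpole"}

    def test_yaml_roundtrip(self, tmp_path):
        spec = syn.ScenarioSpec(n_tips=24, coupling="coupled", seed=11)
        p = tmp_path / "s.yaml"
        spec.to_yaml(p)
        assert syn.ScenarioSpec.from_yaml(p) == spec


def test_shift_set_generator_modes(tree64):
    coupled = syn.simulate_shift_sets(tree64, 8, "coupled", seed=1)
    assert set(coupled["adult"].nodes) == set(coupled["tadpole"].nodes)
    uncoupled = syn.simulate_shift_sets(tree64, 8, "uncoupled", seed=1)
    assert set(uncoupled["adult"].nodes) != set(uncoupled["tadpole"].nodes)
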