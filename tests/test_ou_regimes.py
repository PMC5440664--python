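import numpy as np
import pytest
from scipy.stats import multivariate_normal

from phaseuncouple import ou_regimes as ou
from phaseuncouple import synthetic_data as syn
from phaseuncouple import traits
from phaseuncouple.phylo_io import Phylogeny


class TestHalfLife:
    def test_ln2(self):
        assert ou.half_life(np.log(2.0)) == pytest.approx(1.0)

    def test_formula(self):
        assert ou.half_life(0.1) == pytest.approx(6.9315, abs=1e-4)

    def test_halving_alpha_doubles(self):
        assert ou.half_life(0.2) == pytest.approx(2 * ou.half_life(0.4))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ou.half_life(0.0)


class TestHansenLoglik:
    def test_two_tip_dense_mvn(self):
        tree = Phylogeny.from_newick("(A:1.5,B:1.5);")
        painting = ou.RegimePainting(tree, [])
        a, s2, th = 0.8, 1.3, 0.4
        V = s2 / (2 * a) * np.exp(-a * tree.patristic_matrix()) * \
            (1 - np.exp(-2 * a * tree.shared_depth_matrix()))
        x = np.array([0.3, -0.2])
        ref = multivariate_normal.logpdf(x, mean=np.full(2, th), cov=V)
        assert ou.hansen_loglik(tree, painting, a, s2, [th], x) == \
            pytest.approx(ref, abs=1e-8)

    def test_bm_limit(self, tree20, rng):
        x = traits.simulate_bm(tree20, rng)
        painting = ou.RegimePainting(tree20, [])
        ll_ou = ou.hansen_loglik(tree20, painting, 1e-9, 1.0, [0.0], x)
        ll_bm = traits.bm_loglik(tree20, x, 1.0, m0=0.0)
        assert ll_ou == pytest.approx(ll_bm, abs=1e-5)

    def test_regime_relabel_invariance(self, tree20, rng):
        branches = [int(b) for b in tree20.branches()
                    if tree20.clade_tips(b).size >= 3][:2]
        x = traits.simulate_bm(tree20, rng)
        p1 = ou.RegimePainting(tree20, branches)
        p2 = ou.RegimePainting(tree20, branches[::-1])
        theta = [0.0, 1.0, -1.0]
        # swapping the shift order permutes regime ids 1 and 2
        ll1 = ou.hansen_loglik(tree20, p1, 0.7, 1.0, theta, x)
        ll2 = ou.hansen_loglik(tree20, p2, 0.7, 1.0,
                               [theta[0], theta[2], theta[1]], x)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_invalid_parameters(self, tree20, rng):
        painting = ou.RegimePainting(tree20, [])
        with pytest.raises(ValueError):
            ou.hansen_loglik(tree20, painting, -1.0, 1.0, [0.0],
                             traits.simulate_bm(tree20, rng))

    def test_stationary_variance_of_simulations(self):
        tree = syn.simulate_tree(10, seed=4)
        alpha = 20.0 / tree.T
        sims = traits.simulate_ou(tree, np.random.default_rng(3), alpha, 2.0,
                                  np.zeros(tree.n_nodes), 0.0, nsim=5000)
        assert sims.var() == pytest.approx(2.0 / (2 * alpha), rel=0.1)


class TestPainting:
    def test_shift_consistency(self, tree64):
        b = [int(x) for x in tree64.branches() if not tree64.is_tip(x)][:3]
        p = ou.RegimePainting(tree64, b)
        # painting reconstructable from shifts: each shift branch starts its
        # own regime and regimes are contiguous 0..k
        assert sorted(set(p.branch_regime)) == list(range(p.n_regimes))
        for i, br in enumerate(b):
            assert p.branch_regime[br] == i + 1

    def test_root_shift_rejected(self, tree64):
        with pytest.raises(ValueError):
            ou.RegimePainting(tree64, [tree64.root])


class TestForward:
    def test_single_regime_data_no_shifts(self):
        zero = 0
        for rep in range(20):
            tree = syn.simulate_tree(64, seed=300 + rep)
            x = traits.simulate_ou(tree, np.random.default_rng(400 + rep),
                                   1.5, 1.0, np.zeros(tree.n_nodes), 0.0)
            fits = ou.surface_forward(tree, x)
            zero += len(fits[-1].painting.shift_branches) == 0
        assert zero >= 16  # >= 80% of 20

    def test_exploration_aicc_strictly_decreasing(self, tree64):
        spec = syn.ScenarioSpec(n_tips=64, trait_model="ou", n_shifts=2,
                                coupling="coupled", min_clade=5, seed=0)
        tr = syn.simulate_traits(tree64, spec, seed=11)
        fits = ou.surface_forward(tree64, tr["adult"])
        explore = [f.aicc_explore for f in fits[:-1]]
        assert np.all(np.diff(explore) < 0)


class TestBackward:
    def test_distinct_optima_do_not_collapse(self):
        hits = 0
        for rep in range(5):
            tree = syn.simulate_tree(48, seed=500 + rep)
            spec = syn.ScenarioSpec(n_tips=48, trait_model="ou", n_shifts=2,
                                    coupling="coupled", min_clade=5, seed=0)
            tr = syn.simulate_traits(tree, spec, seed=600 + rep)
            fwd = ou.surface_forward(tree, tr["adult"])[-1]
            bwd, ncol = ou.surface_backward(tree, fwd, tr["adult"])
            assert bwd.aicc <= fwd.aicc + 1e-9
            hits += ncol == 0
        assert hits >= 4

    def test_convergent_regimes_collapse(self):
        spec = syn.ScenarioSpec(n_tips=64, trait_model="ou", n_shifts=2,
                                coupling="coupled", min_clade=5,
                                convergent_regimes=True, seed=0)
        collapsed = 0
        for rep in range(20):
            tree = syn.simulate_tree(64, seed=500 + rep)
            tr = syn.simulate_traits(tree, spec, seed=600 + rep)
            fwd = ou.surface_forward(tree, tr["adult"])[-1]
            _, ncol = ou.surface_backward(tree, fwd, tr["adult"])
            collapsed += ncol >= 1
        assert collapsed >= 14  # >= 70% of 20


class TestConvergencePvalue:
    def test_zero_collapses_gives_p_one(self):
        tree = syn.simulate_tree(16, seed=8)
        x = traits.simulate_ou(tree, np.random.default_rng(1), 1.5, 1.0,
                               np.zeros(tree.n_nodes), 0.0)
        fwd = ou.surface_forward(tree, x)[-1]
        res = ou.convergence_pvalue(tree, fwd, x, nrep=10, seed=2)
        assert res["observed_collapses"] == 0
        assert res["p"] == pytest.approx(1.0)
        assert 1 / 11 <= res["p"] <= 1.0

    def test_nrep_floor(self, tree20, rng):
        x = traits.simulate_bm(tree20, rng)
        fwd = ou.surface_forward(tree20, x)[-1]
        with pytest.raises(ValueError):
            ou.convergence_pvalue(tree20, fwd, x, nrep=5)

    def test_power_on_convergent_data(self):
        """Strongly convergent 4-axis data should yield small p-values."""
        spec = syn.ScenarioSpec(n_tips=24, trait_model="ou", n_shifts=2,
                                n_axes=4, coupling="coupled", min_clade=4,
                                convergent_regimes=True, seed=0)
        assessed, hits, rep = 0, 0, 0
        while assessed < 10 and rep < 16:
            tree = syn.simulate_tree(24, seed=700 + rep)
            tr = syn.simulate_traits(tree, spec, seed=800 + rep)
            rep += 1
            fwd = ou.surface_forward(tree, tr["adult"])[-1]
            if len(fwd.painting.shift_branches) < 2:
                continue  # convergence is undefined without >= 2 regimes
            res = ou.convergence_pvalue(tree, fwd, tr["adult"], nrep=50,
                                        seed=rep)
            assessed += 1
            hits += res["p"] <= 0.1
        assert assessed >= 8
        assert hits / assessed >= 0.7
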