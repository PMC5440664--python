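import numpy as np
import pytest
from scipy.linalg import expm

from phaseuncouple import discrete_correlation as dc
from phaseuncouple import synthetic_data as syn
from phaseuncouple.phylo_io import MISSING, Phylogeny


class TestCtmcLoglik:
    def test_two_tip_matrix_exponential_oracle(self):
        tree = Phylogeny.from_newick("(A:1.2,B:1.2);")
        rates = np.array([0.3, 0.5, 0.2, 0.7])
        Q = dc.build_q(rates, dependent=False)
        pi = dc.stationary_distribution(Q)
        P = expm(Q * 1.2)
        s1 = dc.STATE_INDEX[(0, 1)]
        s2 = dc.STATE_INDEX[(1, 0)]
        oracle = np.log(sum(pi[r] * P[r, s1] * P[r, s2] for r in range(4)))
        mine = dc.ctmc_loglik(tree, [0, 1], [1, 0], rates, dependent=False)
        assert mine == pytest.approx(oracle, abs=1e-8)

    def test_zero_rates_identical_tips(self, toy_tree):
        # no change possible: likelihood is the root prior of the shared state
        ll = dc.ctmc_loglik(toy_tree, [1, 1, 1], [0, 0, 0],
                            np.zeros(4), dependent=False)
        assert ll == pytest.approx(np.log(0.25), abs=1e-10)

    def test_dependent_with_equal_rates_nests_independent(self, tree20):
        a, b = syn.simulate_binary_pair(tree20, 0.4, 1.0, seed=1)
        r4 = np.array([0.3, 0.5, 0.2, 0.7])
        r8 = np.array([r4[0], r4[0], r4[1], r4[1], r4[2], r4[2], r4[3], r4[3]])
        assert dc.ctmc_loglik(tree20, a, b, r4, False) == pytest.approx(
            dc.ctmc_loglik(tree20, a, b, r8, True), abs=1e-10)

    def test_character_swap_symmetry(self, tree20):
        a, b = syn.simulate_binary_pair(tree20, 0.4, 1.0, seed=2)
        r = np.array([0.3, 0.5, 0.2, 0.7])
        swapped = np.array([r[2], r[3], r[0], r[1]])
        assert dc.ctmc_loglik(tree20, a, b, r, False) == pytest.approx(
            dc.ctmc_loglik(tree20, b, a, swapped, False), abs=1e-10)

    def test_long_branch_reaches_stationarity(self):
        rates = np.array([0.3, 0.5, 0.2, 0.7])
        Q = dc.build_q(rates, dependent=False)
        pi = dc.stationary_distribution(Q)
        P = dc._ExpmCache(Q).P(500.0)
        assert np.abs(P - pi[None, :]).max() < 1e-8

    def test_nonbinary_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            dc.ctmc_loglik(toy_tree, [0, 1, 2], [0, 1, 0], np.ones(4), False)


class TestPairLrt:
    def test_perfectly_coupled_pair_significant(self):
        hits = 0
        for rep in range(20):
            tree = syn.simulate_tree(64, seed=30 + rep)
            a, _ = syn.simulate_binary_pair(tree, 0.4, 1.0, seed=rep)
            if len(np.unique(a)) < 2:
                hits += 1  # degenerate draws don't count against power
                continue
            res = dc.pair_lrt(tree, a, a.copy(), starts=2, seed=rep)
            assert res.lr >= 0.0
            hits += res.significant
        assert hits >= 18  # >= 90%

    def test_degenerate_pair_flagged(self, tree20):
        const = np.zeros(tree20.n_tips, dtype=int)
        varying = np.zeros(tree20.n_tips, dtype=int)
        varying[0] = 1
        res = dc.pair_lrt(tree20, const, varying)
        assert res.degenerate

    def test_missing_tips_pruned(self, tree20):
        a, b = syn.simulate_binary_pair(tree20, 0.4, 1.0, seed=3)
        a = a.copy()
        a[:2] = MISSING
        res = dc.pair_lrt(tree20, a, b, starts=1, seed=0)
        assert np.isfinite(res.p) or res.degenerate


class TestSummarize:
    def _mk(self, p, pair=("a", "b")):
        sig = p < 0.05
        return dc.PairTestResult(pair, -10.0, -9.0, 2.0, 4, p, sig)

    def test_worked_counts(self):
        results = [self._mk(0.01)] * 318 + [self._mk(0.5)] * (4255 - 318)
        out = dc.summarize_pairs(results)
        assert out["n_significant"] == 318
        assert out["n_total"] == 4255
        assert out["percent"] == 7.5

    @pytest.mark.parametrize("nsig,total,expected", [(0, 100, 0.0),
                                                     (100, 100, 100.0)])
    def test_extremes(self, nsig, total, expected):
        results = ([self._mk(0.01)] * nsig
                   + [self._mk(0.5)] * (total - nsig))
        assert dc.summarize_pairs(results)["percent"] == expected

    def test_bh_column_and_degenerate_exclusion(self):
        results = [self._mk(0.01), self._mk(0.2),
                   dc.PairTestResult(("x", "y"), np.nan, np.nan, np.nan, 4,
                                     np.nan, False, degenerate=True)]
        out = dc.summarize_pairs(results)
        assert out["n_total"] == 2
        assert "q_bh" in out["table"].columns
        assert np.all(out["table"]["q_bh"] >= out["table"]["p"] - 1e-12)
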