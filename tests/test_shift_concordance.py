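import itertools

import numpy as np
import pytest

from phaseuncouple import shift_concordance as sc
from phaseuncouple import synthetic_data as syn
from phaseuncouple.phylo_io import Phylogeny


class TestSharedRatio:
    def test_identical(self):
        a = sc.ShiftSet("a", [1, 2, 3])
        assert sc.shared_shift_ratio(a, sc.ShiftSet("b", [1, 2, 3])) == 1.0

    def test_disjoint(self):
        a = sc.ShiftSet("a", [1, 2])
        assert sc.shared_shift_ratio(a, sc.ShiftSet("b", [3, 4])) == 0.0

    def test_arithmetic(self):
        a = sc.ShiftSet("a", list(range(7)))
        b = sc.ShiftSet("b", list(range(5, 25)))  # overlap {5,6}: 2/20
        assert sc.shared_shift_ratio(a, b) == pytest.approx(0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.shared_shift_ratio(sc.ShiftSet("a", []), sc.ShiftSet("b", [1]))


class TestNodeConcordance:
    def test_identical_sets_minimal_p(self, tree64):
        nodes = [5, 9, 20, 33]
        a = sc.ShiftSet("a", nodes)
        b = sc.ShiftSet("b", list(nodes))
        res = sc.node_concordance_test(tree64, a, b, nreps=999, seed=0)
        assert res.statistic == 1.0
        assert res.p == pytest.approx(1 / 1000)

    def test_single_shift_null_matches_enumeration(self):
        """|A|=|B|=1: under uniform placement on m eligible nodes the null
        shared ratio is Bernoulli(1/m) — checked against exhaustive
        enumeration of all placements."""
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        pool = sc.eligible_nodes(tree)
        m = pool.size
        exhaustive = np.mean([int(x == y)
                              for x, y in itertools.product(pool, pool)])
        assert exhaustive == pytest.approx(1 / m)
        a = sc.ShiftSet("a", [int(pool[0])])
        b = sc.ShiftSet("b", [int(pool[0])])
        res = sc.node_concordance_test(tree, a, b, nreps=5000, seed=3)
        assert res.null.mean() == pytest.approx(1 / m, abs=0.01)

    def test_too_many_shifts_rejected(self, toy_tree):
        big = list(range(toy_tree.n_nodes)) * 2
        with pytest.raises(ValueError):
            sc.node_concordance_test(toy_tree, sc.ShiftSet("a", big),
                                     sc.ShiftSet("b", [1]))

    def test_seed_reproducibility(self, tree64):
        sets = syn.simulate_shift_sets(tree64, 8, "uncoupled", seed=4)
        r1 = sc.node_concordance_test(tree64, sets["adult"], sets["tadpole"],
                                      nreps=200, seed=9)
        r2 = sc.node_concordance_test(tree64, sets["adult"], sets["tadpole"],
                                      nreps=200, seed=9)
        assert r1.p == r2.p
        assert np.array_equal(r1.null, r2.null)


class TestDirectionConcordance:
    def test_all_same_direction_statistic_one(self, tree64):
        sets = syn.simulate_shift_sets(tree64, 6, "coupled", seed=5)
        a = sets["adult"]
        b = sc.ShiftSet("b", list(a.nodes), dict(a.directions))
        res = sc.direction_concordance_test(tree64, a, b, nreps=200, seed=1)
        assert res.statistic == 1.0

    def test_single_bifurcating_node_bernoulli_half(self, tree64):
        v = next(int(x) for x in tree64.preorder()
                 if len(tree64.children[x]) == 2 and x != tree64.root)
        kids = tree64.children[v]
        a = sc.ShiftSet("a", [v], {v: int(kids[0])})
        b = sc.ShiftSet("b", [v], {v: int(kids[1])})
        res = sc.direction_concordance_test(tree64, a, b, nreps=4000, seed=2)
        # exhaustive: two independent uniform child choices agree w.p. 1/2
        assert res.null.mean() == pytest.approx(0.5, abs=0.03)
        assert set(np.unique(res.null)) <= {0.0, 1.0}

    def test_statistic_bounded(self, tree64):
        sets = syn.simulate_shift_sets(tree64, 8, "coupled", seed=6)
        res = sc.direction_concordance_test(tree64, sets["adult"],
                                            sets["tadpole"], nreps=100,
                                            seed=3)
        assert 0.0 <= res.statistic <= 1.0

    def test_no_shared_nodes_rejected(self, tree64):
        a = sc.ShiftSet("a", [5], {5: int(tree64.children[5][0])}
                        if tree64.children[5] else {})
        b = sc.ShiftSet("b", [])
        with pytest.raises(ValueError):
            sc.direction_concordance_test(tree64, a, b)


class TestBinning:
    def test_interval_assignment(self):
        tree = Phylogeny.from_newick(
            "(((A:5,B:5):17,C:22):8,(D:10,E:10):20);")
        shift_age_22 = [v for v in range(tree.n_nodes)
                        if abs(tree.age[v] - 22) < 1e-9]
        s = sc.ShiftSet("a", shift_age_22)
        out = sc.bin_shifts_by_time(tree, s, width=4.0)
        assert out["counts"][5] == len(shift_age_22)  # [20,24)

    def test_counts_conserved(self, tree64):
        sets = syn.simulate_shift_sets(tree64, 8, "uncoupled", seed=8)
        out = sc.bin_shifts_by_time(tree64, sets["adult"], width=1.0)
        assert out["counts"].sum() == len(sets["adult"].nodes)

    def test_no_shifts_zero_histogram(self, tree64):
        out = sc.bin_shifts_by_time(tree64, sc.ShiftSet("a", []), width=4.0)
        assert out["counts"].sum() == 0


class TestIntervalCorrelation:
    def test_identical(self):
        r, _ = sc.interval_correlation([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert r == pytest.approx(1.0)

    def test_negation(self):
        r, _ = sc.interval_correlation([1, 2, 3, 4.0], [-1, -2, -3, -4.0])
        assert r == pytest.approx(-1.0)

    def test_nan_pairs_dropped(self):
        r, _ = sc.interval_correlation([1, 2, np.nan, 4, 5.0],
                                       [1, 2, 9.0, 4, 5])
        assert r == pytest.approx(1.0)

    def test_independent_poisson_null(self):
        crit = 0.632  # 5% two-sided critical |r| for n=10
        hits = 0
        for rep in range(500):
            g = np.random.default_rng(rep)
            r, _ = sc.interval_correlation(g.poisson(3, 10).astype(float),
                                           g.poisson(3, 10).astype(float))
            hits += abs(r) < crit
        assert hits / 500 == pytest.approx(0.95, abs=0.03)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            sc.interval_correlation([1.0, 2.0], [2.0, 1.0])
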