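import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phaseuncouple import expression_phase as ep
from phaseuncouple import synthetic_data as syn


class TestFpkm:
    def test_formula(self):
        assert ep.compute_fpkm(100, 1000, 1e6) == pytest.approx(100.0)

    def test_zero_counts(self):
        assert ep.compute_fpkm(0, 1000, 1e6) == 0.0

    def test_doubling_total_halves(self):
        a = ep.compute_fpkm(50, 500, 1e6)
        b = ep.compute_fpkm(50, 500, 2e6)
        assert b == pytest.approx(a / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ep.compute_fpkm(10, 0, 1e6)


def table(rows):
    return pd.DataFrame(rows, columns=["gene", "fpkm_adult", "fpkm_tadpole"])


class TestClassify:
    def test_threshold_examples(self):
        t = table([("g1", 8.0, 4.0),    # ratio 2 -> adult-biased
                   ("g2", 1.0, 4.0),    # ratio 0.25 -> tadpole-biased
                   ("g3", 5.0, 5.0),    # ratio 1 -> even
                   ("g4", 0.1, 0.2)])   # below floor in both
        res = ep.classify_phase_bias(t)
        got = dict(zip(t["gene"], res.table["phase_class"]))
        assert got == {"g1": "adult-biased", "g2": "tadpole-biased",
                       "g3": "even", "g4": "unclassifiable"}

    def test_floor_rule_single_phase(self):
        t = table([("g1", 9.0, 0.0), ("g2", 0.0, 9.0)])
        res = ep.classify_phase_bias(t)
        assert list(res.table["phase_class"]) == ["adult-biased",
                                                  "tadpole-biased"]

    def test_partition_conservation(self):
        t = syn.simulate_expression(syn.ScenarioSpec(n_genes=500, seed=3))
        res = ep.classify_phase_bias(t)
        assert sum(res.counts.values()) == len(t)

    def test_threshold_monotonicity(self):
        t = syn.simulate_expression(syn.ScenarioSpec(n_genes=500, seed=4))
        loose = ep.classify_phase_bias(t, hi=1.6, lo=0.4)
        strict = ep.classify_phase_bias(t, hi=2.5, lo=0.25)
        def biased(r):
            return r.counts["adult-biased"] + r.counts["tadpole-biased"]
        assert biased(strict) <= biased(loose)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            ep.classify_phase_bias(table([("g", 1.0, 1.0)]), hi=0.4, lo=1.6)


class TestKeywordFlag:
    def test_substring_match(self):
        flags = ep.keyword_flag(["osteoclast differentiation"], ["osteoclast"])
        assert flags[0]

    def test_empty_annotation(self):
        assert not ep.keyword_flag([""], ["osteoclast"])[0]

    def test_case_insensitive(self):
        assert ep.keyword_flag(["Keratin filament"], ["keratin"])[0]

    def test_matches_regex_scan_oracle(self):
        t = syn.simulate_expression(syn.ScenarioSpec(n_genes=300, seed=5))
        terms = syn.MORPH_TERMS
        mine = ep.keyword_flag(t["annotation"].tolist(), terms)
        pattern = re.compile("|".join(re.escape(x) for x in terms), re.I)
        oracle = np.array([bool(pattern.search(a)) for a in t["annotation"]])
        assert np.array_equal(mine, oracle)

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            ep.keyword_flag(["x"], [])


class TestZtest:
    def test_equal_proportions(self):
        out = ep.proportion_ztest(10, 100, 10, 100)
        assert out["z"] == 0.0
        assert out["p"] == 1.0

    def test_pooled_formula_oracle(self):
        k1, n1, k2, n2 = 50, 100, 10, 100
        pooled = (k1 + k2) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z_hand = (k1 / n1 - k2 / n2) / se
        out = ep.proportion_ztest(k1, n1, k2, n2)
        assert out["z"] == pytest.approx(z_hand, abs=1e-12)

    def test_swap_negates_z(self):
        a = ep.proportion_ztest(30, 80, 10, 90)
        b = ep.proportion_ztest(10, 90, 30, 80)
        assert a["z"] == pytest.approx(-b["z"])
        assert a["p"] == pytest.approx(b["p"])

    def test_degenerate_pooled(self):
        out = ep.proportion_ztest(0, 50, 0, 60)
        assert out == {"z": 0.0, "p": 1.0}

    def test_invalid(self):
        with pytest.raises(ValueError):
            ep.proportion_ztest(5, 0, 1, 10)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(fpkm=st.lists(st.tuples(st.floats(0, 1e4), st.floats(0, 1e4)),
                     min_size=1, max_size=40))
def test_classification_partitions_any_table(fpkm):
    t = pd.DataFrame({"gene": [f"g{i}" for i in range(len(fpkm))],
                      "fpkm_adult": [a for a, _ in fpkm],
                      "fpkm_tadpole": [b for _, b in fpkm]})
    res = ep.classify_phase_bias(t)
    assert sum(res.counts.values()) == len(t)
    assert set(res.table["phase_class"]) <= set(ep.CLASSES)


def test_full_report_ztests_biased_vs_even():
    t = syn.simulate_expression(syn.ScenarioSpec(n_genes=2000, seed=6))
    report = ep.phase_bias_report(t, terms=syn.MORPH_TERMS)
    assert set(report["counts"]) == set(ep.CLASSES)
    # planted enrichment: biased classes carry more morphology flags
    z = report["ztests"]["adult-biased_vs_even"]
    assert z["z"] > 0 and z["p"] < 0.05
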