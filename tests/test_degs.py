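"""Normalization, probe collapsing and differential-expression screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netmod import (DegConfig, collapse_probes, differential_expression,
                    filter_degs, gen_expression, quantile_normalize)
from oracles import oracle_bh


class TestQuantileNormalize:
    def test_hand_example(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        for col in out:
            assert list(out[col]) == [2.5, 3.5, 4.5]

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"s1": [3.0, 1.0, 2.0], "s2": [3.0, 1.0, 2.0]})
        assert np.allclose(quantile_normalize(m), m)

    def test_column_sorted_vectors_equal_and_idempotent(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        once = quantile_normalize(m)
        ref = np.sort(once["a"].to_numpy())
        for col in once:
            assert np.allclose(np.sort(once[col].to_numpy()), ref)
        assert np.allclose(quantile_normalize(once), once, atol=1e-12)

    def test_ties_get_mean_of_rank_values(self):
        m = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        # tied values in s1 share the mean of the rank-1 and rank-2 targets
        assert out["s1"][0] == out["s1"][1] == pytest.approx(
            (out["s2"].sort_values().iloc[0] + out["s2"].sort_values().iloc[1]) / 2)

    def test_single_sample_warns(self, caplog):
        m = pd.DataFrame({"s1": [1.0, 2.0]})
        with caplog.at_level("WARNING"):
            out = quantile_normalize(m)
        assert out.equals(m)


class TestCollapseProbes:
    def test_rules(self):
        m = pd.DataFrame({"s1": [5.0, 7.0, 9.0], "s2": [5.0, 7.0, 9.0]},
                         index=["p1", "p2", "p3"])
        pm = {"p1": ["A"], "p2": ["A"], "p3": ["A", "B"]}
        out = collapse_probes(m, pm)
        assert list(out.index) == ["A"]
        assert out.loc["A", "s1"] == 7.0  # highest-mean probe wins; p3 dropped

    def test_pass_through_and_empty_mapping(self):
        m = pd.DataFrame({"s1": [1.0, 2.0]}, index=["p1", "p2"])
        out = collapse_probes(m, {"p1": ["X"], "p2": []})
        assert list(out.index) == ["X"]
        assert out.loc["X", "s1"] == 1.0

    def test_tie_breaks_to_smaller_probe_id(self):
        m = pd.DataFrame({"s1": [4.0, 4.0]}, index=["pB", "pA"])
        out = collapse_probes(m, {"pA": ["G"], "pB": ["G"]})
        assert out.loc["G"].name == "G"
        assert (m.loc["pA"] == out.loc["G"]).all()

    def test_nothing_left_errors(self):
        m = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        with pytest.raises(ValueError):
            collapse_probes(m, {"p1": ["A", "B"]})


def _two_group_frame(values1, values2):
    cols = [f"t{i}" for i in range(len(values1))] + [f"n{i}" for i in range(len(values2))]
    m = pd.DataFrame([values1 + values2], index=["G1"], columns=cols)
    groups = pd.Series(["tumor"] * len(values1) + ["normal"] * len(values2), index=cols)
    return m, groups


class TestDifferentialExpression:
    def test_welch_hand_example(self):
        m, groups = _two_group_frame([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        out = differential_expression(m, groups, contrast=("tumor", "normal"))
        row = out.iloc[0]
        assert row["logFC"] == pytest.approx(-2.0)
        # t = -2/sqrt(2/3), df = 4, p = 2·sf(2.449, 4)
        assert row["p"] == pytest.approx(2 * stats.t.sf(2.449489, 4), rel=1e-4)

    def test_identical_groups_floor_gives_p_one(self):
        m, groups = _two_group_frame([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        out = differential_expression(m, groups, contrast=("tumor", "normal"))
        assert out.iloc[0]["logFC"] == 0.0
        assert out.iloc[0]["p"] == 1.0

    def test_small_group_errors(self):
        m, groups = _two_group_frame([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(m, groups, contrast=("tumor", "normal"))

    def test_bh_adjustment_properties(self):
        expr, labels, _ = gen_expression(300, 4, 4, de_fraction=0.0, seed=2)
        out = differential_expression(expr, labels, contrast=("tumor", "normal"))
        assert (out["adj_p"] >= out["p"] - 1e-15).all()
        assert np.allclose(np.sort(out["adj_p"]),
                           np.sort(oracle_bh(list(out["p"]))), atol=1e-12)

    def test_null_pvalues_uniform(self):
        expr, labels, _ = gen_expression(5000, 10, 10, de_fraction=0.0, seed=17)
        out = differential_expression(expr, labels, contrast=("tumor", "normal"))
        frac = float((out["p"] < 0.05).mean())
        mc_sd = np.sqrt(0.05 * 0.95 / 5000)
        assert abs(frac - 0.05) <= 2 * mc_sd + 1e-9

    def test_planted_simulation_fdr_and_power_consistency(self):
        expr, labels, truth = gen_expression(2000, 10, 10, 0.1, 2.0, 1.0, seed=7)
        out = differential_expression(expr, labels, contrast=("tumor", "normal"))
        up, down = filter_degs(out)
        called = up | down
        planted = truth["up"] | truth["down"]
        tp = len(called & planted)
        assert (len(called) - tp) / max(len(called), 1) <= 0.1
        # recall should agree with the Welch test's own theoretical power at
        # the realized BH threshold (noncentral t, ncp = lfc/sqrt(2σ²/n))
        alpha = float(out.loc[out["adj_p"] < 0.05, "p"].max())
        tstar = stats.t.isf(alpha / 2, 18)
        power = stats.nct.sf(tstar, 18, 2 / np.sqrt(0.2)) + stats.nct.cdf(-tstar, 18, 2 / np.sqrt(0.2))
        recall = tp / len(planted)
        assert recall == pytest.approx(power, abs=0.05)
        # direction of every true positive matches the planted sign
        assert up & planted <= truth["up"]
        assert down & planted <= truth["down"]


class TestFilterDegs:
    @pytest.mark.parametrize("logfc,adj_p,expected", [
        (0.6, 0.01, "up"),
        (-0.6, 0.01, "down"),
        (0.4, 0.001, "ns"),
        (0.6, 0.06, "ns"),
    ])
    def test_threshold_rules(self, logfc, adj_p, expected):
        rows = pd.DataFrame({"gene": ["G"], "logFC": [logfc],
                             "p": [adj_p / 2], "adj_p": [adj_p]})
        up, down = filter_degs(rows)
        got = "up" if "G" in up else "down" if "G" in down else "ns"
        assert got == expected

    def test_up_down_disjoint(self):
        expr, labels, _ = gen_expression(500, 5, 5, 0.2, 1.5, 1.0, seed=3)
        out = differential_expression(expr, labels, contrast=("tumor", "normal"))
        up, down = filter_degs(out)
        assert not (up & down)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            filter_degs(pd.DataFrame(columns=["gene", "logFC", "p", "adj_p"]))
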