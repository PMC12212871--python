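"""Subgroup definition, patterns, contribution fractions, relative change."""

import numpy as np
import pandas as pd
import pytest

from pdprs.strata import (assign_subgroups, contribution_fractions, relative_change,
                          score_phenotype_associations, subgroup_patterns)


def _scores(n=100, k=3, seed=0):
    rng = np.random.default_rng(seed)
    parts = rng.normal(size=(n, k))
    df = pd.DataFrame(parts, columns=[f"c{i}" for i in range(k)],
                      index=pd.Index([f"i{j}" for j in range(n)], name="IID"))
    df.insert(0, "OVERALL", df.sum(axis=1))
    return df


class TestAssignSubgroups:
    def test_top_5_percent_count_without_ties(self):
        scores = _scores(100)
        a = assign_subgroups(scores, q=0.05)
        assert int(a.high_risk.sum()) == 5

    def test_overlapping_membership_allowed(self):
        n = 40
        df = pd.DataFrame({"c1": np.arange(n, dtype=float),
                           "c2": np.arange(n, dtype=float)},
                          index=pd.Index([f"i{j}" for j in range(n)], name="IID"))
        df.insert(0, "OVERALL", df["c1"] + df["c2"])
        a = assign_subgroups(df, q=0.1)
        top = a.high_risk[a.high_risk].index
        assert a.membership.loc[top, ["c1", "c2"]].all(axis=1).all()

    def test_high_risk_member_below_all_thresholds_in_no_subgroup(self):
        scores = _scores(200, seed=3)
        # give one individual a huge overall PRS via a cluster not thresholded on
        scores.loc["i0", ["c0", "c1", "c2"]] = scores[["c0", "c1", "c2"]].median()
        scores.loc["i0", "OVERALL"] = scores["OVERALL"].max() + 10
        a = assign_subgroups(scores, q=0.05)
        assert a.high_risk["i0"]
        assert not a.membership.loc["i0"].any()
        for c in a.clusters:
            assert "i0" in a.remaining(c)

    def test_monotone_in_q(self):
        scores = _scores(500, seed=5)
        a5 = assign_subgroups(scores, q=0.05)
        a10 = assign_subgroups(scores, q=0.10)
        assert set(a5.high_risk[a5.high_risk].index) <= set(
            a10.high_risk[a10.high_risk].index)

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            assign_subgroups(_scores(), q=0.6)


class TestPatterns:
    def test_counting(self):
        scores = _scores(3)
        a = assign_subgroups(scores, q=0.4)
        a.high_risk[:] = True
        a.membership.loc[:] = False
        a.membership.loc["i0", "c0"] = True
        a.membership.loc["i1", "c0"] = True
        a.membership.loc["i2", ["c0", "c1"]] = True
        counts = subgroup_patterns(a)
        assert counts["c0"] == 2
        assert counts["c0,c1"] == 1

    def test_empty_pattern_counted_and_totals_match(self):
        scores = _scores(300, seed=9)
        a = assign_subgroups(scores, q=0.1)
        counts = subgroup_patterns(a)
        assert counts.sum() == int(a.high_risk.sum())
        # someone in the top overall tail is usually below all component tails
        assert "" in counts.index


class TestContributions:
    def test_fractions_sum_to_one(self):
        scores = _scores(400, seed=11)
        a = assign_subgroups(scores, q=0.1)
        fr, _ = contribution_fractions(scores, a)
        np.testing.assert_allclose(fr.sum(axis=1), 1.0, atol=1e-10)

    def test_equal_shifted_components_give_uniform_fractions(self):
        n = 60
        rng = np.random.default_rng(1)
        base = rng.normal(size=n)
        df = pd.DataFrame({f"c{i}": base for i in range(9)},
                          index=pd.Index([f"i{j}" for j in range(n)], name="IID"))
        df.insert(0, "OVERALL", df.sum(axis=1))
        a = assign_subgroups(df, q=0.2)
        fr, _ = contribution_fractions(df, a)
        np.testing.assert_allclose(fr.to_numpy(), 1 / 9, atol=1e-10)

    def test_degenerate_component_warns_and_zeroes(self):
        scores = _scores(100, seed=2)
        scores["c2"] = 1.0
        a = assign_subgroups(scores, q=0.1)
        with pytest.warns(UserWarning, match="degenerate"):
            fr, _ = contribution_fractions(scores, a)
        assert (fr["c2"] == 0).all()

    def test_focal_subgroup_has_higher_focal_fraction(self, tiny_sim):
        """On simulated data, each cluster's mean contribution is larger
        inside its own subgroup than among the remaining high-risk set."""
        from pdprs.pipeline import decompose_replicate
        _, scores, _, _, _ = decompose_replicate(tiny_sim)
        a = assign_subgroups(scores, q=0.05)
        _, summary = contribution_fractions(scores, a)
        for c in [c for c in a.clusters if c != "OTHERS"]:
            block = summary[(summary["subgroup"] == c) & (summary["cluster"] == c)]
            m = block.set_index("group")["mean"]
            assert m["subgroup"] > m["remaining"]


class TestRelativeChange:
    def _assignment(self, values):
        n = len(values)
        scores = pd.DataFrame({"OVERALL": np.arange(n, dtype=float),
                               "c": np.arange(n, dtype=float)},
                              index=pd.Index([f"i{j}" for j in range(n)], name="IID"))
        return assign_subgroups(scores, q=0.4)

    def test_arithmetic(self):
        vals = pd.Series({"i0": 0.0, "i1": 0.0, "i2": 0.0, "i3": 0.0,
                          "i4": 1.0, "i5": 1.5, "i6": 1.5})
        scores = pd.DataFrame(
            {"OVERALL": [0, 1, 2, 3, 4, 5, 6.], "c": [0, 0, 0, 0, 0, 9, 9.]},
            index=vals.index)
        a = assign_subgroups(scores, q=0.49)
        # high-risk: i4..i6; subgroup c: i5, i6; remaining: i4
        rc = relative_change(vals, a, "c")
        sd = vals.loc[["i4", "i5", "i6"]].std()
        assert rc == pytest.approx((1.5 - 1.0) / sd)

    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(4)
        n = 200
        scores = pd.DataFrame({"OVERALL": rng.normal(size=n),
                               "c": rng.normal(size=n)},
                              index=pd.Index([f"i{j}" for j in range(n)], name="IID"))
        a = assign_subgroups(scores, q=0.2)
        vals = pd.Series(3.14, index=scores.index)
        with pytest.warns(UserWarning):
            assert np.isnan(relative_change(vals, a, "c"))

    def test_binary_prevalence_difference(self):
        idx = pd.Index([f"i{j}" for j in range(10)], name="IID")
        scores = pd.DataFrame({"OVERALL": np.arange(10, dtype=float),
                               "c": [0] * 8 + [9, 9.]}, index=idx)
        a = assign_subgroups(scores, q=0.45)
        vals = pd.Series([0] * 5 + [0, 1, 0, 1, 1], index=idx, dtype=float)
        rc = relative_change(vals, a, "c", kind="binary")
        hr = a.high_risk[a.high_risk].index
        expected = (vals.loc[a.subgroup("c")].mean()
                    - vals.loc[a.remaining("c")].mean()) / vals.loc[hr].std()
        assert rc == pytest.approx(expected)

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        n = 300
        scores = pd.DataFrame({"OVERALL": rng.normal(size=n),
                               "c": rng.normal(size=n)},
                              index=pd.Index([f"i{j}" for j in range(n)], name="IID"))
        a = assign_subgroups(scores, q=0.1)
        vals = pd.Series(rng.normal(size=n), index=scores.index)
        base = relative_change(vals, a, "c")
        assert relative_change(5.0 * vals - 2.0, a, "c") == pytest.approx(base)


class TestAssociations:
    def test_linear_recovers_unit_slope(self, rng):
        n = 2_000
        s = pd.DataFrame({"s": rng.normal(size=n)})
        ph = pd.DataFrame({"y": s["s"] + rng.normal(size=n)})
        tab = score_phenotype_associations(s, ph)
        row = tab.iloc[0]
        assert row["coefficient"] == pytest.approx(1.0, abs=0.1)
        assert row["p"] < 1e-10

    def test_null_bonferroni_rate(self, rng):
        n, reps = 400, 200
        flags = 0
        for _ in range(reps):
            s = pd.DataFrame({"s": rng.normal(size=n)})
            ph = pd.DataFrame({"y": rng.normal(size=n)})
            flags += int(score_phenotype_associations(s, ph)["significant"].iloc[0])
        assert flags / reps <= 0.05 + 0.03  # Bonferroni level for 1 test is 0.05

    def test_logistic_recovers_slope(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 * x)))
        y = rng.binomial(1, p)
        tab = score_phenotype_associations(pd.DataFrame({"s": x}),
                                           pd.DataFrame({"d": y}),
                                           binary={"d": True})
        assert tab["coefficient"].iloc[0] == pytest.approx(0.5, abs=0.15)
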