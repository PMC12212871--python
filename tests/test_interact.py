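"""Residualization, INT, interaction LRT, FDR, stratified risk and RERI."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdprs.interact import (InteractionTest, bh_fdr, int_transform, interaction_test,
                            reri, residualize_trait, stratified_risk)


class TestResidualize:
    def test_orthogonal_covariates_return_centered_trait(self, rng):
        n = 2_000
        y = rng.normal(size=n)
        cov = pd.DataFrame({"x": rng.normal(size=n)})
        resid = residualize_trait(y, cov)
        np.testing.assert_allclose(resid, y - y.mean(), atol=0.15)
        assert np.corrcoef(resid, cov["x"])[0, 1] == pytest.approx(0, abs=1e-10)

    def test_exact_linear_combination_gives_zero_residuals(self, rng):
        cov = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
        y = 2 * cov["a"] - cov["b"] + 3
        resid = residualize_trait(y, cov)
        np.testing.assert_allclose(resid, 0, atol=1e-10)

    def test_residual_variance_equals_noise_variance(self, rng):
        n = 20_000
        age = rng.normal(size=n)
        noise = rng.normal(0, 0.7, size=n)
        resid = residualize_trait(2 * age + noise, pd.DataFrame({"age": age}))
        assert np.var(resid) == pytest.approx(0.49, rel=0.05)

    def test_collinear_design_names_columns(self, rng):
        a = rng.normal(size=50)
        cov = pd.DataFrame({"a": a, "twice_a": 2 * a})
        with pytest.raises(ValueError, match="twice_a"):
            residualize_trait(rng.normal(size=50), cov)

    def test_logistic_family_residuals_bounded(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-x)))
        resid = residualize_trait(y, pd.DataFrame({"x": x}), family="logistic")
        assert np.all(np.abs(resid) <= 1)


class TestIntTransform:
    def test_middle_of_three_maps_to_zero(self):
        out = int_transform([10.0, -3.0, 4.0])
        assert out[2] == pytest.approx(0.0, abs=1e-12)

    def test_monotone(self, rng):
        x = rng.normal(size=101)
        out = int_transform(x)
        assert np.all(np.diff(out[np.argsort(x)]) > 0)

    def test_blom_formula_n5(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        out = int_transform(x)
        r = stats.rankdata(x)
        np.testing.assert_allclose(out, stats.norm.ppf((r - 0.375) / 5.25))

    def test_ties_get_average_ranks(self):
        out = int_transform([1.0, 1.0, 2.0])
        assert out[0] == out[1]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            int_transform([1.0, 1.0])

    def test_depends_on_ranks_only(self, rng):
        x = rng.normal(size=60)
        np.testing.assert_allclose(int_transform(x), int_transform(np.exp(x)))


class TestInteractionTest:
    def test_lrt_definition_and_nonnegativity(self, rng):
        n = 300
        prs, mod = rng.normal(size=n), rng.normal(size=n)
        y = prs + mod + 0.5 * prs * mod + rng.normal(size=n)
        res = interaction_test(prs, mod, outcome=y, mode="linear")
        assert res.lrt >= 0
        assert res.p < 0.01
        assert res.coefficient == pytest.approx(0.5, abs=0.2)

    def test_type_one_error_near_nominal(self, rng):
        """Zero-interaction generative model: ~5% rejections over 500 reps."""
        n, rejections = 150, 0
        for _ in range(500):
            prs, mod = rng.normal(size=n), rng.normal(size=n)
            y = prs + mod + rng.normal(size=n)
            rejections += interaction_test(prs, mod, outcome=y, mode="linear").p < 0.05
        assert 0.03 <= rejections / 500 <= 0.075

    def test_survival_mode_detects_interaction(self, rng):
        n = 3_000
        prs, mod = rng.normal(size=n), rng.normal(size=n)
        hazard = np.exp(0.3 * prs + 0.3 * mod + 0.5 * prs * mod)
        t = rng.exponential(1 / hazard)
        cens = np.quantile(t, 0.7)
        event = (t <= cens).astype(int)
        time = np.minimum(t, cens)
        res = interaction_test(prs, mod, time=time, event=event, mode="survival")
        assert res.converged
        assert res.p < 0.01
        assert res.coefficient == pytest.approx(0.5, abs=0.2)

    def test_pipeline_invariant_to_monotone_rescaling_of_moderator(self, rng):
        """INT uses ranks only, so interaction results on INT-transformed
        traits match any monotone rescaling of those traits."""
        n = 500
        prs = rng.normal(size=n)
        trait = rng.normal(size=n) + 0.2 * prs
        y = prs + trait + 0.3 * prs * trait + rng.normal(size=n)
        m1 = int_transform(trait)
        m2 = int_transform(np.exp(2 * trait) + 5)
        r1 = interaction_test(prs, m1, outcome=y, mode="linear")
        r2 = interaction_test(prs, m2, outcome=y, mode="linear")
        assert r1.coefficient == pytest.approx(r2.coefficient, abs=1e-10)
        assert r1.p == pytest.approx(r2.p, abs=1e-10)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q, flags = bh_fdr(np.array([0.01, 0.02, 0.03, 0.9]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.9])
        assert flags.tolist() == [True, True, True, False]

    def test_single_p_identity(self):
        q, _ = bh_fdr(np.array([0.2]))
        assert q[0] == pytest.approx(0.2)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=50)
        q, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    def test_null_false_flag_proportion_controlled(self, rng):
        """Fully null scan (29 traits x 10 scores): expected flag share <= level."""
        props = []
        for _ in range(200):
            _, flags = bh_fdr(rng.uniform(size=290))
            props.append(flags.mean())
        assert np.mean(props) <= 0.05


class TestStratifiedRiskAndReri:
    def _fixture(self, rates, n_cell=100, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (s, e), rate in rates.items():
            for _ in range(n_cell):
                ev = rng.uniform() < rate
                rows.append((rng.uniform(1, 5), int(ev), s, e))
        df = pd.DataFrame(rows, columns=["time", "event", "sub", "exp"])
        return df

    def test_arithmetic_on_known_counts(self):
        # deterministic cell case counts: 10/100 exposed vs 5/100 unexposed
        event = np.r_[np.ones(10), np.zeros(90), np.ones(5), np.zeros(95)]
        time = np.ones(200)
        sub = np.zeros(200, bool)
        exposure = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        sr = stratified_risk(time, event, sub, exposure)
        assert sr.arr_remaining == pytest.approx(0.05)
        assert sr.absolute_risk.loc["remaining", "exposed"] == pytest.approx(0.10)

    def test_null_cells_give_unit_hazard_ratios(self):
        df = self._fixture({(s, e): 0.2 for s in (0, 1) for e in (0, 1)},
                           n_cell=400, seed=1)
        sr = stratified_risk(df["time"], df["event"], df["sub"] == 1, df["exp"] == 1)
        assert np.nanmax(np.abs(np.log(sr.hazard_ratios["hr"]))) < 0.5
        assert abs(sr.arr_subgroup) < 0.1 and abs(sr.arr_remaining) < 0.1

    def test_reri_arithmetic(self):
        sr = stratified_risk(np.ones(4), np.zeros(4), np.array([1, 1, 0, 0], bool),
                             np.array([1, 0, 1, 0], bool))
        sr.absolute_risk.loc["subgroup", "exposed"] = 0.16
        sr.absolute_risk.loc["subgroup", "unexposed"] = 0.12
        sr.absolute_risk.loc["remaining", "exposed"] = 0.12
        sr.absolute_risk.loc["remaining", "unexposed"] = 0.10
        sr.counts.loc[:, :] = 100
        res = reri(sr)
        # ARR_sub 0.04, ARR_rem 0.02, R00 0.10 -> RERI 0.2
        assert res.reri == pytest.approx(0.2)

    def test_reri_null_when_arrs_equal(self):
        sr = stratified_risk(np.ones(4), np.zeros(4), np.array([1, 1, 0, 0], bool),
                             np.array([1, 0, 1, 0], bool))
        for s in ("subgroup", "remaining"):
            sr.absolute_risk.loc[s, "exposed"] = 0.2
            sr.absolute_risk.loc[s, "unexposed"] = 0.1
        sr.counts.loc[:, :] = 200
        res = reri(sr)
        assert res.reri == pytest.approx(0.0)
        assert res.p > 0.9

    def test_zero_reference_risk_flagged(self):
        sr = stratified_risk(np.ones(4), np.zeros(4), np.array([1, 1, 0, 0], bool),
                             np.array([1, 0, 1, 0], bool))
        sr.absolute_risk.loc["remaining", "unexposed"] = 0.0
        assert not reri(sr).ok

    def test_delta_se_close_to_bootstrap(self):
        """Delta-method SE within 15% of a 2,000-resample bootstrap."""
        rates = {(1, 1): 0.30, (1, 0): 0.12, (0, 1): 0.20, (0, 0): 0.10}
        df = self._fixture(rates, n_cell=400, seed=7)
        sub, exp_ = (df["sub"] == 1).to_numpy(), (df["exp"] == 1).to_numpy()
        sr = stratified_risk(df["time"], df["event"], sub, exp_)
        delta_se = reri(sr).se

        rng = np.random.default_rng(99)
        boot = []
        ev = df["event"].to_numpy()
        cells = [sub & exp_, sub & ~exp_, ~sub & exp_, ~sub & ~exp_]
        for _ in range(2_000):
            ars = []
            for cell in cells:
                sample = rng.choice(ev[cell], size=cell.sum(), replace=True)
                ars.append(sample.mean())
            a_se, a_su, a_re, a_ru = ars
            if a_ru > 0:
                boot.append((a_se - a_su - a_re + a_ru) / a_ru)
        assert delta_se == pytest.approx(np.std(boot), rel=0.15)

    def test_nonconvergent_fit_flagged_not_raised(self):
        res = interaction_test(np.zeros(30), np.zeros(30),
                               outcome=np.random.default_rng(0).normal(size=30),
                               mode="linear")
        assert isinstance(res, InteractionTest)
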