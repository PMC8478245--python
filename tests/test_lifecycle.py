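"""Lifetime earnings projection, returns translation, and OLS estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecdeval as e
from ecdeval.lifecycle import LifecycleError


def _flat_profile(w, a0=16, a1=64):
    ages = np.arange(a0, a1 + 1)
    return e.WageProfile(ages, np.full(ages.size, float(w)))


def _immortal(max_age=100):
    ages = np.arange(0, max_age + 1)
    return e.LifeTable(ages, np.ones(ages.size))


class TestPDV:
    def test_undiscounted_no_mortality_is_plain_sum(self):
        p = _flat_profile(100.0, 16, 25)
        assert e.pdv_lifetime_earnings(p, _immortal(), 0.0, 2) == pytest.approx(1000.0)

    @given(
        st.floats(1.0, 1e5),
        st.floats(0.001, 0.5),
        st.integers(16, 30),
        st.integers(40, 64),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_annuity_closed_form(self, w, r, a0, a1):
        """Constant wage, no mortality: PDV equals the geometric-series
        annuity sum_k w/(1+r)^k to 1e-10 relative."""
        anchor = 2
        p = _flat_profile(w, a0, a1)
        pdv = e.pdv_lifetime_earnings(p, _immortal(), r, anchor)
        d = 1.0 / (1.0 + r)
        k0, k1 = a0 - anchor, a1 - anchor
        closed = w * (d**k0 - d ** (k1 + 1)) / (1.0 - d)
        assert pdv == pytest.approx(closed, rel=1e-10)

    def test_strictly_decreasing_in_discount_rate(self, profile, lifetable):
        rates = [0.0, 0.03, 0.05, 0.10, 0.25]
        pdvs = [e.pdv_lifetime_earnings(profile, lifetable, r, 2) for r in rates]
        assert all(a > b for a, b in zip(pdvs, pdvs[1:]))

    def test_increasing_in_wages_decreasing_in_mortality(self, lifetable):
        p = _flat_profile(100.0)
        base = e.pdv_lifetime_earnings(p, lifetable, 0.05, 2)
        richer = e.pdv_lifetime_earnings(p.scaled(1.1), lifetable, 0.05, 2)
        assert richer > base
        deadlier = e.LifeTable(
            lifetable.ages, lifetable.survival * 0.9, lifetable.anchor_age
        )
        # keep the anchor normalised
        surv = deadlier.survival.copy()
        surv[0] = 1.0
        deadlier = e.LifeTable(lifetable.ages, surv, lifetable.anchor_age)
        assert e.pdv_lifetime_earnings(p, deadlier, 0.05, 2) < base

    def test_missing_ages_rejected(self):
        short = e.LifeTable(np.arange(0, 40), np.ones(40))
        with pytest.raises(LifecycleError, match="covers ages"):
            e.pdv_lifetime_earnings(_flat_profile(1.0), short, 0.05, 2)

    def test_calibrated_profile_hits_published_pdv(self, profile, lifetable):
        pdv = e.pdv_lifetime_earnings(profile, lifetable, 0.05, 2)
        assert pdv == pytest.approx(13219.0, abs=0.5)


class TestImpacts:
    @pytest.mark.parametrize(
        "effect, expected",
        [(0.52, 0.2064), (0.34, 0.135), (0.0, 0.0)],
    )
    def test_wage_impact(self, effect, expected, returns):
        assert e.wage_impact(effect, returns) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "effect, expected",
        [(0.52, 0.93), (0.34, 0.61), (0.0, 0.0)],
    )
    def test_schooling_impact(self, effect, expected, returns):
        assert e.schooling_impact(effect, returns) == pytest.approx(expected, abs=5e-3)

    @given(st.floats(0, 2), st.floats(0.1, 3))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_effect(self, effect, factor):
        r = e.ReturnsModel()
        assert e.wage_impact(effect * factor, r) == pytest.approx(
            factor * e.wage_impact(effect, r), rel=1e-12, abs=1e-12
        )
        assert e.schooling_impact(effect * factor, r) == pytest.approx(
            factor * e.schooling_impact(effect, r), rel=1e-12, abs=1e-12
        )


class TestSchoolingCost:
    def test_zero_years_costs_nothing(self, assumptions):
        assert e.schooling_cost(0.0, assumptions) == 0.0

    def test_calibrated_benchmark_costs(self, assumptions, returns):
        """0.93 extra years -> US$35; the smaller arm's 0.61 years -> US$23."""
        g = e.schooling_cost(e.schooling_impact(0.52, returns), assumptions)
        m = e.schooling_cost(e.schooling_impact(0.34, returns), assumptions)
        assert g == pytest.approx(35.0, abs=1e-9)
        assert m == pytest.approx(35.0 * 0.34 / 0.52, rel=1e-12)
        assert round(m) == 23

    def test_linearity_and_monotonicity(self, assumptions):
        one = e.schooling_cost(1.0, assumptions)
        assert e.schooling_cost(2.0, assumptions) == pytest.approx(2 * one, rel=1e-12)
        assert e.schooling_cost(0.5, assumptions) < one

    def test_undiscounted_mode_is_larger(self, assumptions):
        flat = assumptions.with_(discount_schooling=False)
        assert e.schooling_cost(1.0, flat) > e.schooling_cost(1.0, assumptions)

    def test_negative_years_rejected(self, assumptions):
        with pytest.raises(LifecycleError):
            e.schooling_cost(-0.1, assumptions)


class TestBenchmarkAssumptions:
    def test_defaults(self, assumptions):
        assert assumptions.discount_rate == 0.05
        assert assumptions.tax_rate == 0.146
        assert assumptions.schooling_cost_share == 0.15

    def test_calibration_is_exact_at_reference(self, assumptions):
        assert e.schooling_cost(0.52 * 1.79, assumptions) == pytest.approx(
            35.0, abs=1e-12
        )

    def test_invalid_rates_rejected(self):
        with pytest.raises(LifecycleError):
            e.EconAssumptions(discount_rate=-0.01)
        with pytest.raises(LifecycleError):
            e.EconAssumptions(tax_rate=1.5)


class TestEstimateReturns:
    def test_recovers_true_returns_within_3_se(self):
        panel = e.gen_returns_panel(e.SyntheticConfig(seed=11))
        est = e.estimate_returns(panel)
        assert abs(est.wage_return_per_sd - 0.397) <= 3 * est.wage_return_se
        assert abs(est.schooling_return_per_sd - 1.79) <= 3 * est.schooling_return_se

    def test_null_wage_return_covered_by_ci(self):
        panel = e.gen_returns_panel(e.SyntheticConfig(seed=3, true_wage_return=0.0))
        est = e.estimate_returns(panel)
        assert abs(est.wage_return_per_sd) <= 1.96 * est.wage_return_se

    def test_noiseless_panel_recovered_exactly(self):
        cfg = e.SyntheticConfig(seed=5, wage_noise_sd=0.0, schooling_noise_sd=0.0)
        est = e.estimate_returns(e.gen_returns_panel(cfg))
        assert est.wage_return_per_sd == pytest.approx(0.397, abs=1e-8)
        assert est.schooling_return_per_sd == pytest.approx(1.79, abs=1e-8)
        assert est.wage_return_se == pytest.approx(0.0, abs=1e-8)

    def test_adjustment_removes_confounding(self):
        """Parental education is correlated with cognition; dropping it from
        the covariate set biases the wage coefficient upward."""
        panel = e.gen_returns_panel(e.SyntheticConfig(seed=7))
        adj = e.estimate_returns(panel)
        unadj = e.estimate_returns(
            panel, covariates=["female", "wave", "baseline_grade", "interview_month"]
        )
        assert unadj.wage_return_per_sd > adj.wage_return_per_sd + 2 * adj.wage_return_se

    def test_collinear_columns_named(self):
        panel = e.gen_returns_panel(e.SyntheticConfig(seed=1, panel_n=200))
        panel["dup"] = panel["parental_education"] * 2.0
        with pytest.raises(LifecycleError, match="dup|parental_education"):
            e.estimate_returns(panel)

    def test_degenerate_cognition_rejected(self):
        panel = e.gen_returns_panel(e.SyntheticConfig(seed=1, panel_n=100))
        panel["cognition_sd"] = 0.0
        with pytest.raises(LifecycleError, match="distinct"):
            e.estimate_returns(panel)

    def test_cluster_robust_option_changes_se_only(self):
        panel = e.gen_returns_panel(e.SyntheticConfig(seed=9, panel_n=1000))
        panel["village"] = np.arange(len(panel)) % 25
        plain = e.estimate_returns(panel, covariates=["parental_education", "female"])
        clustered = e.estimate_returns(
            panel, covariates=["parental_education", "female"], cluster_col="village"
        )
        assert clustered.wage_return_per_sd == pytest.approx(
            plain.wage_return_per_sd, rel=1e-12
        )
        assert clustered.wage_return_se != plain.wage_return_se


class TestFileReaders:
    def test_wage_profile_and_lifetable_roundtrip(self, tmp_path, profile, lifetable):
        ppath = tmp_path / "profile.csv"
        pd.DataFrame(
            {"age": profile.ages, "mean_annual_wage_usd": profile.mean_wage}
        ).to_csv(ppath, index=False)
        again = e.read_wage_profile(ppath)
        assert np.allclose(again.mean_wage, profile.mean_wage)

        lpath = tmp_path / "lt.csv"
        pd.DataFrame({"age": lifetable.ages, "survival": lifetable.survival}).to_csv(
            lpath, index=False
        )
        again = e.read_lifetable(lpath, anchor_age=2)
        assert np.allclose(again.survival, lifetable.survival)

    def test_lifetable_from_qx(self, tmp_path):
        ages = np.arange(0, 5)
        pd.DataFrame({"age": ages, "qx": [0.1, 0.0, 0.5, 0.0, 1.0]}).to_csv(
            tmp_path / "qx.csv", index=False
        )
        lt = e.read_lifetable(tmp_path / "qx.csv")
        assert np.allclose(lt.survival, [1.0, 0.9, 0.9, 0.45, 0.45])
        anchored = e.read_lifetable(tmp_path / "qx.csv", anchor_age=1)
        assert anchored.survival[0] == 1.0
        assert anchored.survival_at(np.array([3])) == pytest.approx(0.5)
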