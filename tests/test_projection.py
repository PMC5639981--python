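"""Deterministic projection: growth summaries, compounding, group means."""

import numpy as np
import pytest

from cheforecast import (
    ForecastSet,
    GdpProjection,
    IncomeGroup,
    compute_decline,
    cumulative_decline,
    predict_che,
    project_gdp_2040,
    project_group_che,
    summarize_growth,
)
from cheforecast.projection import GroupGrowthSummary, baseline_group_che


def _proj(cid, group, rate, base=1000.0, years=(2015, 2021)):
    yrs = list(range(years[0], years[1] + 1))
    return GdpProjection(cid, group, yrs, [base * (1 + rate) ** (y - yrs[0]) for y in yrs])


class TestSummarizeGrowth:
    def test_shared_rate_has_zero_sd(self):
        projs = [_proj(f"C{i}", "LIC", 0.045) for i in range(4)]
        out = summarize_growth(projs)
        s = out[IncomeGroup.LIC]
        assert s.mean_rate == pytest.approx(0.045, abs=1e-12)
        assert s.sd_rate == pytest.approx(0.0, abs=1e-12)
        assert s.n_countries == 4

    def test_two_country_sample_sd(self):
        projs = [_proj("A", "LMIC", 0.03), _proj("B", "LMIC", 0.05)]
        s = summarize_growth(projs)[IncomeGroup.LMIC]
        assert s.mean_rate == pytest.approx(0.04, abs=1e-12)
        assert s.sd_rate == pytest.approx(0.014142135623730954, abs=1e-9)

    def test_absent_group_omitted(self):
        out = summarize_growth([_proj("A", "HIC", 0.02)])
        assert IncomeGroup.LIC not in out
        assert set(out) == {IncomeGroup.HIC}

    def test_ols_annualization_matches_endpoint_for_geometric(self):
        projs = [_proj("A", "UMIC", 0.041)]
        e = summarize_growth(projs, annualization="endpoint")[IncomeGroup.UMIC]
        o = summarize_growth(projs, annualization="ols_log")[IncomeGroup.UMIC]
        assert o.mean_rate == pytest.approx(e.mean_rate, abs=1e-10)


class TestProjectGdp:
    class Row:
        gdp_c_base, base_year, horizon_year = 1000.0, 2013, 2040

    def test_zero_rate_constant(self):
        g = GroupGrowthSummary(IncomeGroup.LIC, 0.0, 0.0, 3)
        assert project_gdp_2040(self.Row, g) == pytest.approx(1000.0)

    def test_closed_form(self):
        g = GroupGrowthSummary(IncomeGroup.LIC, 0.045, 0.029, 3)
        assert project_gdp_2040(self.Row, g) == pytest.approx(1000 * 1.045**27)

    def test_group_rate_not_country_rate(self, fitted, small_world):
        """Two same-group countries with equal base GDP end at equal 2040 GDP."""
        _, _, forecasts, gdp = small_world
        growth = summarize_growth(gdp)
        df = forecasts.data[forecasts.data["income_group"] == IncomeGroup.LIC].head(2).copy()
        df["gdp_c_base"] = 700.0
        rows = list(df.itertuples())
        vals = [project_gdp_2040(r, growth[IncomeGroup.LIC]) for r in rows]
        assert vals[0] == vals[1]


class TestProjectGroupChe:
    def test_group_mean_is_exact_arithmetic_mean(self, fitted, small_world):
        _, _, forecasts, _ = small_world
        growth = summarize_growth(small_world[3])
        out = project_group_che(fitted, forecasts, growth)
        for proj in out.values():
            vals = [proj.country_points[c] for c in sorted(proj.country_points)]
            assert proj.che_point == sum(vals) / len(vals)  # exact, not approx

    def test_single_country_group(self, fitted, small_world):
        _, _, forecasts, gdp = small_world
        growth = summarize_growth(gdp)
        one = ForecastSet(forecasts.data[forecasts.data["country_id"] == "LIC000"])
        out = project_group_che(fitted, one, growth)
        assert list(out) == [IncomeGroup.LIC]
        (che,) = out[IncomeGroup.LIC].country_points.values()
        assert out[IncomeGroup.LIC].che_point == che

    def test_permutation_invariance(self, fitted, small_world):
        _, _, forecasts, gdp = small_world
        growth = summarize_growth(gdp)
        shuffled = ForecastSet(
            forecasts.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        a = project_group_che(fitted, forecasts, growth)
        b = project_group_che(fitted, shuffled, growth)
        for g in a:
            assert a[g].che_point == b[g].che_point
            assert a[g].country_points == b[g].country_points

    def test_raising_oop_raises_every_group_mean(self, fitted, small_world):
        """With a positive OOP coefficient, shifting every country's OOP
        forecast upward strictly raises each group's projected CHE."""
        _, _, forecasts, gdp = small_world
        growth = summarize_growth(gdp)
        assert fitted.beta_[1] > 0
        bumped_df = forecasts.data.copy()
        for col in ("oop_exp_mean", "oop_exp_lo", "oop_exp_hi"):
            bumped_df[col] = 0.5 + 0.5 * bumped_df[col]
        base = project_group_che(fitted, forecasts, growth)
        bumped = project_group_che(fitted, ForecastSet(bumped_df), growth)
        for g in base:
            assert bumped[g].che_point > base[g].che_point

    def test_missing_growth_group_excluded(self, fitted, small_world, caplog):
        _, _, forecasts, gdp = small_world
        growth = summarize_growth(gdp)
        growth.pop(IncomeGroup.HIC)
        with caplog.at_level("WARNING"):
            out = project_group_che(fitted, forecasts, growth)
        assert IncomeGroup.HIC not in out

    def test_blup_option_shifts_country_predictions(self, fitted, small_world):
        _, _, forecasts, gdp = small_world
        growth = summarize_growth(gdp)
        pop = project_group_che(fitted, forecasts, growth, use_blup=False)
        blup = project_group_che(fitted, forecasts, growth, use_blup=True)
        diffs = [
            blup[g].country_points[c] - pop[g].country_points[c]
            for g in pop for c in pop[g].country_points
        ]
        assert any(abs(d) > 1e-6 for d in diffs)


class TestDeclineAndBaseline:
    def test_equal_endpoints_no_decline(self):
        assert compute_decline(0.02, 0.02, 27) == pytest.approx(0.0)

    def test_inverse_identity_with_cumulative(self):
        r = compute_decline(0.031, 0.018, 27)
        assert cumulative_decline(r, 27) == pytest.approx(1 - 0.018 / 0.031, rel=1e-12)

    def test_published_magnitude(self):
        """A 1.7%/year decline removes ~37% of starting incidence in 27 years."""
        assert round(100 * cumulative_decline(0.017, 27)) == 37

    def test_fitted_and_observed_baselines_both_available(self, fitted, small_world):
        panel, *_ = small_world
        fit_base = baseline_group_che(fitted, panel, fitted=True)
        obs_base = baseline_group_che(fitted, panel, fitted=False)
        assert set(fit_base) == set(obs_base)
        for g in fit_base:
            assert 0 < fit_base[g] < 1 and 0 < obs_base[g] < 1

    def test_baseline_matches_manual_prediction(self, fitted, small_world):
        panel, *_ = small_world
        base = baseline_group_che(fitted, panel, fitted=True)
        last = panel.last_observations()
        for g, expected in base.items():
            rows = last[last["income_group"] == g]
            vals = [predict_che(fitted, r["oop_exp"], r["hex_gdp"], r["gdp_c"])
                    for _, r in rows.iterrows()]
            assert expected == pytest.approx(sum(vals) / len(vals), abs=1e-15)
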