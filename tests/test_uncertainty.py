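"""Monte Carlo engine: distribution fits, sampling, aggregation, summaries."""

import numpy as np
import pytest
from scipy import stats

from cheforecast import (
    IncomeGroup,
    beta_from_mean_ui,
    gamma_from_mean_sd,
    gap_closing_probability,
    percentile_ui,
    run_monte_carlo,
    sample_coefficients,
    target_probabilities,
)
from cheforecast.errors import DomainError, ValidationError
from cheforecast.projection import GroupGrowthSummary, summarize_growth
from cheforecast.synthetic import default_config
from cheforecast import (
    fit_che_model,
    generate_forecasts,
    generate_gdp_projections,
    generate_panel,
)


class TestBetaFit:
    def test_symmetric_ui_gives_symmetric_shapes(self):
        p = beta_from_mean_ui(0.5, 0.3, 0.7)
        assert p.alpha == pytest.approx(p.beta, rel=1e-6)

    def test_mean_constraint_exact(self):
        p = beta_from_mean_ui(0.3, 0.22, 0.41)
        assert p.alpha / (p.alpha + p.beta) == pytest.approx(0.3, abs=1e-12)

    def test_quantile_round_trip_on_true_beta_triples(self):
        """Triples generated by an actual beta distribution are recovered:
        the fitted parameters reproduce the 2.5/97.5 quantiles."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = rng.uniform(1.5, 40, 2)
            mean = a / (a + b)
            lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
            p = beta_from_mean_ui(mean, lo, hi)
            qlo, qhi = stats.beta.ppf([0.025, 0.975], p.alpha, p.beta)
            assert qlo == pytest.approx(lo, abs=1e-5)
            assert qhi == pytest.approx(hi, abs=1e-5)

    def test_zero_width_returns_point_mass(self):
        p = beta_from_mean_ui(0.3, 0.3, 0.3)
        assert p.point_mass
        draws = p.sample(10, np.random.default_rng(0))
        assert np.all(draws == 0.3)

    @pytest.mark.parametrize("mean, lo, hi", [(0.3, 0.35, 0.4), (0.0, 0.0, 0.1),
                                              (0.5, 0.2, 1.0)])
    def test_invalid_triples_rejected(self, mean, lo, hi):
        with pytest.raises(DomainError):
            beta_from_mean_ui(mean, lo, hi)


class TestGammaFit:
    def test_published_growth_inputs(self):
        """Moment matching the 4.5% (SD 2.9%) growth summary."""
        p = gamma_from_mean_sd(4.5, 2.9)
        assert p.shape == pytest.approx(2.4078478002378123, rel=1e-12)
        assert p.scale == pytest.approx(1.8688888888888888, rel=1e-12)

    def test_mean_equal_sd_is_exponential(self):
        assert gamma_from_mean_sd(2.0, 2.0).shape == pytest.approx(1.0)

    def test_moment_round_trip(self):
        p = gamma_from_mean_sd(0.045, 0.029)
        assert p.mean == pytest.approx(0.045, rel=1e-12)
        assert p.sd == pytest.approx(0.029, rel=1e-12)

    @pytest.mark.parametrize("mean, sd", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_rejected(self, mean, sd):
        with pytest.raises(DomainError):
            gamma_from_mean_sd(mean, sd)


class TestSampleCoefficients:
    def test_zero_vcov_reproduces_mean_exactly(self, fitted):
        saved = fitted.beta_vcov_
        try:
            fitted.beta_vcov_ = np.zeros((4, 4))
            draws = sample_coefficients(fitted, 100, seed=3)
            assert np.all(draws == fitted.beta_)
        finally:
            fitted.beta_vcov_ = saved

    def test_seed_determinism(self, fitted):
        a = sample_coefficients(fitted, 1000, seed=5)
        b = sample_coefficients(fitted, 1000, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_sample_mean_within_clt_bound(self, fitted):
        n = 100_000
        draws = sample_coefficients(fitted, n, seed=11)
        se = np.sqrt(np.diag(fitted.beta_vcov_))
        bound = 4 * se / np.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - fitted.beta_) < bound)

    def test_sample_covariance_converges(self, fitted):
        draws = sample_coefficients(fitted, 200_000, seed=2)
        np.testing.assert_allclose(np.cov(draws.T), fitted.beta_vcov_,
                                   atol=5e-4, rtol=0.15)

    def test_non_psd_matrix_rejected(self, fitted):
        saved = fitted.beta_vcov_
        try:
            fitted.beta_vcov_ = np.diag([1.0, 1.0, 1.0, -1e-3])
            with pytest.raises(ValidationError, match="positive semi-definite"):
                sample_coefficients(fitted, 10, seed=0)
        finally:
            fitted.beta_vcov_ = saved


class TestPercentileUI:
    def test_linear_interpolation_rule(self):
        lo, hi = percentile_ui(np.arange(1, 101))
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_constant_array(self):
        assert percentile_ui(np.full(50, 0.7)) == (0.7, 0.7)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.random(501)
        assert percentile_ui(x) == percentile_ui(rng.permutation(x))

    def test_needs_two_samples(self):
        with pytest.raises(ValidationError):
            percentile_ui([1.0])


class TestGapProbability:
    def test_dominating_array(self):
        assert gap_closing_probability(np.full(10, 0.02), np.full(10, 0.01)) == 1.0

    def test_identical_arrays_strict_tie_convention(self):
        x = np.linspace(0, 1, 10)
        assert gap_closing_probability(x, x) == 0.0

    def test_symmetric_independent_arrays_near_half(self):
        rng = np.random.default_rng(3)
        n = 40_000
        a, b = rng.normal(0, 1, n), rng.normal(0, 1, n)
        assert gap_closing_probability(a, b) == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            gap_closing_probability(np.ones(3), np.ones(4))


@pytest.fixture(scope="module")
def mc_samples(fitted, small_world, growth):
    panel, _, forecasts, _ = small_world
    return run_monte_carlo(fitted, forecasts, growth, n=5000, seed=17,
                           baseline_covariates=panel.last_observations())


class TestMonteCarlo:
    def test_group_arrays_are_exact_row_means(self, mc_samples):
        for g, members in mc_samples.group_members().items():
            stacked = np.vstack([mc_samples.per_country[c] for c in sorted(members)])
            np.testing.assert_array_equal(mc_samples.per_group[g], stacked.mean(axis=0))

    def test_all_draws_are_proportions(self, mc_samples):
        for arr in mc_samples.per_country.values():
            assert np.all((arr > 0) & (arr < 1))

    def test_seed_determinism(self, fitted, small_world, growth):
        panel, _, forecasts, _ = small_world
        kw = dict(n=1500, seed=23, baseline_covariates=panel.last_observations())
        s1 = run_monte_carlo(fitted, forecasts, growth, **kw)
        s2 = run_monte_carlo(fitted, forecasts, growth, **kw)
        for c in s1.per_country:
            np.testing.assert_array_equal(s1.per_country[c], s2.per_country[c])
        for g in s1.decline_per_group:
            np.testing.assert_array_equal(s1.decline_per_group[g],
                                          s2.decline_per_group[g])

    def test_degenerate_sources_collapse_to_deterministic_projection(
            self, fitted, small_world):
        """Zero-width forecast UIs, zero coefficient vcov and zero growth SD
        remove every randomness source: all trials coincide with the
        deterministic point projection and probabilities are 0/1."""
        from cheforecast import ForecastSet, project_group_che

        panel, _, forecasts, gdp = small_world
        df = forecasts.data.copy()
        for p in ("oop_exp", "hex_gdp"):
            df[f"{p}_lo"] = df[f"{p}_mean"]
            df[f"{p}_hi"] = df[f"{p}_mean"]
        point_fc = ForecastSet(df)
        growth0 = {g: GroupGrowthSummary(g, s.mean_rate, 0.0, s.n_countries)
                   for g, s in summarize_growth(gdp).items()}
        saved = fitted.beta_vcov_
        try:
            fitted.beta_vcov_ = np.zeros((4, 4))
            samples = run_monte_carlo(fitted, point_fc, growth0, n=300, seed=1)
        finally:
            fitted.beta_vcov_ = saved
        deterministic = project_group_che(fitted, point_fc, growth0)
        for g, arr in samples.per_group.items():
            assert np.all(arr == arr[0])
            assert arr[0] == pytest.approx(deterministic[g].che_point, abs=1e-12)
            lo, hi = percentile_ui(arr)
            assert lo == hi == pytest.approx(arr[0])
        report = target_probabilities(samples)
        assert set(report.probabilities.values()) <= {0.0, 1.0}

    def test_decline_rates_reconstruct_endpoints(self, mc_samples):
        for g, decline in mc_samples.decline_per_group.items():
            base = mc_samples.baseline_per_group[g]
            end = mc_samples.per_group[g]
            np.testing.assert_allclose(base * (1 - decline) ** 27, end, rtol=1e-10)

    def test_point_mass_forecast_country_is_constant_in_trials(
            self, fitted, small_world, growth):
        from cheforecast import ForecastSet

        _, _, forecasts, _ = small_world
        df = forecasts.data.head(3).copy()
        df.loc[df.index[0], "oop_exp_lo"] = df.loc[df.index[0], "oop_exp_mean"]
        df.loc[df.index[0], "oop_exp_hi"] = df.loc[df.index[0], "oop_exp_mean"]
        samples = run_monte_carlo(fitted, ForecastSet(df), growth, n=200, seed=5)
        assert len(samples.per_country) == 3


class TestTargetReport:
    def test_direct_count(self):
        from cheforecast.uncertainty import McSamples

        arr = np.array([0.004, 0.006, 0.012, 0.020])
        samples = McSamples(n=4, seed=0, per_country={"X": arr},
                            per_group={IncomeGroup.LIC: arr})
        report = target_probabilities(samples, [0.01], decline_reference=None)
        assert report.probabilities[(IncomeGroup.LIC, 0.01)] == 0.5

    def test_threshold_above_all_samples(self, mc_samples):
        report = target_probabilities(mc_samples, [0.999])
        assert all(v == 1.0 for (g, t), v in report.probabilities.items())

    def test_monotone_in_threshold(self, mc_samples):
        report = target_probabilities(mc_samples)
        for g in report.groups:
            probs = [report.probabilities[(g, t)] for t in report.thresholds]
            assert probs == sorted(probs)

    def test_gap_probabilities_present_against_umic(self, mc_samples):
        report = target_probabilities(mc_samples)
        assert IncomeGroup.LIC in report.gap_probabilities
        assert IncomeGroup.UMIC not in report.gap_probabilities
        assert 0.0 <= report.gap_probabilities[IncomeGroup.LIC] <= 1.0

    def test_bad_threshold_rejected(self, mc_samples):
        with pytest.raises(ValidationError):
            target_probabilities(mc_samples, [1.5])


def test_group_ui_covers_generator_truth():
    """Calibration: when forecast UIs reflect the true sampling noise, the
    95% group UI contains the generator's true 2040 group CHE in >= 85% of
    seeded replicates (using per-country BLUPs, since the projection targets
    the same countries the model was fitted on)."""
    reps, hits, total = 50, 0, 0
    for rep in range(reps):
        cfg = default_config(
            n_countries_per_group={"LIC": 6, "LMIC": 6, "UMIC": 6, "HIC": 6},
            years=(2006, 2013), seed=40_000 + rep,
        )
        panel, truth = generate_panel(cfg)
        forecasts = generate_forecasts(truth, ui_width_factor=1.0)
        model = fit_che_model(panel)
        growth = summarize_growth(generate_gdp_projections(truth))
        samples = run_monte_carlo(model, forecasts, growth, n=2000,
                                  seed=rep, use_blup=True)
        true_groups = truth.true_group_che_2040()
        for g, arr in samples.per_group.items():
            lo, hi = percentile_ui(arr)
            hits += lo <= true_groups[g] <= hi
            total += 1
    assert hits / total >= 0.85
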