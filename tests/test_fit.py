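"""Constrained Bass estimation: recovery, determinism, sensitivity, stability."""

import numpy as np
import pytest
from scipy import optimize

from phrdiffusion import (
    AdoptionSeries,
    BassDiffusion,
    BassParams,
    FitConfig,
    bass_cdf,
    datasets,
    fit_policy_targets,
    motivation_ratio,
    sensitivity_analysis,
    stability_check,
)


def exact_series(params: BassParams, years) -> AdoptionSeries:
    return AdoptionSeries(
        list(years),
        [bass_cdf(params, float(y - params.start_year)) for y in years],
    )


class TestFit:
    @pytest.mark.parametrize("p_true", [0.002, 0.01, 0.05])
    @pytest.mark.parametrize("q_true", [0.1, 0.25, 0.4])
    def test_noise_free_parameter_recovery(self, p_true, q_true):
        truth = BassParams(p=p_true, q=q_true, start_year=2004)
        series = exact_series(truth, (2008, 2011, 2013))
        result = BassDiffusion(series, start_year=2004).fit()
        assert result.params.p == pytest.approx(p_true, abs=1e-3)
        assert result.params.q == pytest.approx(q_true, abs=1e-3)
        assert result.objective < 1e-12
        assert result.feasible

    def test_noise_free_recovery_is_tight(self):
        truth = BassParams(p=0.005, q=0.25, start_year=2004)
        series = exact_series(truth, (2008, 2011, 2013))
        result = BassDiffusion(series, start_year=2004).fit()
        assert result.params.p == pytest.approx(0.005, abs=1e-4)
        assert result.params.q == pytest.approx(0.25, abs=1e-4)

    def test_observed_series_start_2001_is_feasible(self, observed_series):
        result = BassDiffusion(observed_series, start_year=2001).fit()
        assert result.feasible
        assert np.max(np.abs(result.resid_pp)) <= 2.0
        assert 50 < result.params.q_over_p < 500

    def test_two_point_series_fits_exactly(self):
        series = AdoptionSeries([2010, 2015], [0.04, 0.12])
        result = BassDiffusion(series, start_year=2004).fit()
        assert np.max(np.abs(result.resid)) < 1e-8

    def test_matches_independent_global_optimizer(self, observed_series):
        """Cross-check the grid+refine fit against a brute-force search."""
        model = BassDiffusion(observed_series, start_year=2001)
        result = model.fit()

        def sse(x):
            return model._sse(np.asarray(x))

        x_opt = optimize.brute(
            sse,
            ranges=[(-4.0, -1.0), (0.0, 0.6)],
            Ns=80,
            finish=optimize.fmin,
        )
        assert result.objective <= sse(x_opt) + 1e-10
        assert result.params.p == pytest.approx(10 ** x_opt[0], rel=1e-3)
        assert result.params.q == pytest.approx(x_opt[1], rel=1e-3)

    def test_deterministic_reruns(self, observed_series):
        r1 = BassDiffusion(observed_series, start_year=2001).fit()
        r2 = BassDiffusion(observed_series, start_year=2001).fit()
        assert r1.params == r2.params
        assert r1.objective == r2.objective
        assert r1.to_dict() == r2.to_dict()

    def test_objective_not_worse_than_any_grid_start(self, observed_series):
        result = BassDiffusion(observed_series, start_year=2004).fit()
        assert result.objective <= result.grid_objective_min + 1e-15

    def test_feasibility_flag_matches_residual_band(self, observed_series):
        for start in (2001, 2007):
            result = BassDiffusion(observed_series, start_year=start).fit()
            within = np.max(np.abs(result.resid)) <= result.config.constraint_band
            assert result.feasible == within

    def test_degenerate_series_warns_but_fits(self):
        series = AdoptionSeries([2008, 2011, 2013], [0.10, 0.10, 0.10])
        result = BassDiffusion(series, start_year=2004).fit()
        assert result.warnings
        assert result.params.p > 0

    def test_start_year_after_observations_rejected(self, observed_series):
        with pytest.raises(ValueError):
            BassDiffusion(observed_series, start_year=2008)
        with pytest.raises(ValueError):
            BassDiffusion(AdoptionSeries([2010], [0.1]), start_year=2004)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FitConfig(constraint_band=0.0)
        with pytest.raises(ValueError):
            FitConfig(p_bounds=(0.5, 0.1))


class TestSensitivity:
    def test_coefficient_pattern_across_start_years(self, observed_series):
        table = sensitivity_analysis(
            observed_series, [2001, 2004, 2007], FitConfig(start_year=2001)
        )
        frame = table.frame
        assert list(frame["start_year"]) == [2001, 2004, 2007]
        # later introduction -> more external, less internal influence
        assert frame["q"].is_monotonic_decreasing
        assert frame["p"].is_monotonic_increasing
        assert frame["q_over_p"].is_monotonic_decreasing

    def test_single_start_equals_direct_fit(self, observed_series):
        table = sensitivity_analysis(observed_series, [2004])
        direct = BassDiffusion(observed_series, start_year=2004).fit()
        assert table[2004].params == direct.params

    def test_ratio_column_is_definitional(self, observed_series):
        table = sensitivity_analysis(observed_series, [2001, 2004])
        for start, res in table.results.items():
            row = table.frame.set_index("start_year").loc[start]
            assert row["q_over_p"] == pytest.approx(motivation_ratio(res.params))

    def test_failing_start_year_does_not_abort_others(self, observed_series):
        table = sensitivity_analysis(observed_series, [2010, 2004])
        assert 2010 in table.errors
        assert 2004 in table.results


class TestStability:
    def test_exact_series_gives_zero_difference(self):
        truth = BassParams(p=0.005, q=0.25, start_year=2004)
        series = exact_series(truth, (2008, 2011, 2013))
        check = stability_check(series, FitConfig(start_year=2004), 2020)
        assert check.abs_difference < 1e-6

    def test_invariant_to_input_order(self, observed_series):
        shuffled = AdoptionSeries([2013, 2008, 2011], [0.1717, 0.0516, 0.0980])
        cfg = FitConfig(start_year=2004)
        a = stability_check(observed_series, cfg, 2020)
        b = stability_check(shuffled, cfg, 2020)
        assert a.abs_difference == b.abs_difference

    def test_reports_both_fits_and_horizon_values(self, observed_series):
        check = stability_check(observed_series, FitConfig(start_year=2004), 2020)
        assert len(check.reduced.model.series) == 2
        assert check.full_forecast == pytest.approx(
            bass_cdf(check.full.params, 16.0)
        )

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            stability_check(
                AdoptionSeries([2008, 2011], [0.05, 0.10]),
                FitConfig(start_year=2004),
                2020,
            )


class TestPolicyTargets:
    def test_mu_fit_contrasts_with_observed_2004_fit(self, observed_series):
        cfg = FitConfig(start_year=2004)
        mu = fit_policy_targets(datasets.mu_target_series(), cfg)
        obs = BassDiffusion(observed_series, start_year=2004).fit(cfg)
        assert mu.label == "MU targets"
        assert mu.feasible
        assert mu.params.p < obs.params.p
        assert mu.params.q_over_p > obs.params.q_over_p

    def test_targets_on_exact_curve_recovered(self):
        truth = BassParams(p=0.003, q=0.2, start_year=2004)
        targets = exact_series(truth, (2014, 2017))
        result = fit_policy_targets(targets, FitConfig(start_year=2004))
        assert result.params.p == pytest.approx(0.003, abs=1e-6)
        assert result.params.q == pytest.approx(0.2, abs=1e-5)

    def test_single_milestone_rejected(self):
        with pytest.raises(ValueError):
            fit_policy_targets(AdoptionSeries([2014], [0.05]), FitConfig(start_year=2004))
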