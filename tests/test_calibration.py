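"""Tests for the rate -> probability inversion and schedule extrapolation."""

import numpy as np
import pandas as pd
import pytest

from idmproj.calibration import (
    EpiSeries,
    estimate_schedule,
    extrapolate_schedule,
    rates_to_probabilities,
)
from idmproj.errors import (
    CoverageError,
    DegenerateCohortError,
    InconsistentRatesError,
)
from idmproj.idm import TransitionProbabilities, TransitionSchedule
from idmproj.synthetic import GeneratorConfig, make_truth, observe, recovery_error


def make_panel_frame(years, prev, inc, mc, ma, location="X", sex="both"):
    rows = []
    for y, p, l, c, a in zip(years, prev, inc, mc, ma):
        for measure, v in (("prevalence", p), ("incidence", l), ("deaths_cause", c), ("deaths_all", a)):
            rows.append((location, sex, measure, y, v, v, v))
    return pd.DataFrame(rows, columns=["location", "sex", "measure", "year", "value", "lower", "upper"])


class TestRatesToProbabilities:
    def test_direct_evaluation(self):
        out = rates_to_probabilities(prev=100, inc=20, mort_cause=18, mort_all=900)
        assert out.i == pytest.approx(2.0020e-4, abs=1e-7)
        assert out.m_I == pytest.approx(0.18, abs=1e-7)
        assert out.m_S == pytest.approx(8.8288e-3, abs=1e-7)

    def test_all_zero_rates(self):
        assert rates_to_probabilities(0, 0, 0, 0) == TransitionProbabilities(0, 0, 0)

    def test_saturated_prevalence_rejected(self):
        with pytest.raises(DegenerateCohortError):
            rates_to_probabilities(100000, 0, 0, 0)

    def test_cause_exceeding_all_cause_rejected(self):
        with pytest.raises(InconsistentRatesError):
            rates_to_probabilities(100, 20, 900, 18)

    def test_exponential_risk_option_close_to_identity_at_small_rates(self):
        a = rates_to_probabilities(100, 20, 18, 900)
        b = rates_to_probabilities(100, 20, 18, 900, annual_risk="exponential")
        assert b.i == pytest.approx(a.i, rel=1e-3)
        assert b.m_I < a.m_I  # 1 - exp(-r) < r


class TestEstimateSchedule:
    def test_noise_free_round_trip_constant_truth(self, constant_truth, noisefree_panel):
        key = constant_truth.keys()[0]
        est = estimate_schedule(noisefree_panel, key)
        err = recovery_error(constant_truth, {key: est})
        assert err.worst <= 1e-10

    def test_noise_free_round_trip_trending_truth(self, multikey_panel):
        cfg = GeneratorConfig(
            n_locations=2, sexes=("male", "female"), year_start=1990, year_end=2019,
            mode="loglinear", seed=11,
        )
        truth = make_truth(cfg)
        est = {key: estimate_schedule(multikey_panel, key) for key in multikey_panel.keys()}
        assert recovery_error(truth, est).worst <= 1e-10

    def test_missing_year_names_the_gap(self, noisefree_panel):
        df = noisefree_panel.frame
        broken = df[~((df["year"] == 2005) & (df["measure"] == "incidence"))]
        with pytest.raises(CoverageError, match="2005"):
            EpiSeries(broken)

    def test_noisy_recovery_small_mean_bias(self, constant_truth):
        """Under 5% CV lognormal noise the estimator is nearly unbiased."""
        key = constant_truth.keys()[0]
        true_s = constant_truth.schedules[key]
        sums = {p: 0.0 for p in ("i", "m_S", "m_I")}
        n_rep = 50
        for r in range(n_rep):
            panel = observe(constant_truth, noise_cv=0.05, seed=1000 + r)
            est = estimate_schedule(panel, key)
            for p in sums:
                sums[p] += np.mean(getattr(est, p) / getattr(true_s, p) - 1.0)
        for p, total in sums.items():
            assert abs(total / n_rep) <= 0.02, f"parameter {p} biased"


class TestExtrapolateSchedule:
    def constant_schedule(self):
        return TransitionSchedule.constant(TransitionProbabilities(0.01, 0.008, 0.3), 2000, 2019)

    @pytest.mark.parametrize("method", ["hold_last", "loglinear"])
    def test_constant_schedule_extends_flat(self, method):
        ext = extrapolate_schedule(self.constant_schedule(), 2030, method=method)
        assert ext.end_year == 2030
        assert np.allclose(ext.i, 0.01, rtol=1e-12)
        assert np.allclose(ext.m_S, 0.008, rtol=1e-12)
        assert np.allclose(ext.m_I, 0.3, rtol=1e-12)

    def test_loglinear_recovers_geometric_trend(self):
        years = np.arange(2010, 2020)
        i = 0.01 * 1.02 ** (years - 2010)
        sched = TransitionSchedule(years, i, np.full(10, 0.01), np.full(10, 0.3))
        ext = extrapolate_schedule(sched, 2024, method="loglinear", window=10)
        expected = 0.01 * 1.02**14
        assert ext[2024].i == pytest.approx(expected, abs=1e-9)

    def test_observed_years_unchanged(self):
        sched = self.constant_schedule()
        ext = extrapolate_schedule(sched, 2040, method="loglinear")
        assert np.array_equal(ext.i[: len(sched)], sched.i)
        assert np.array_equal(ext.years[: len(sched)], sched.years)

    def test_horizon_not_beyond_last_year_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_schedule(self.constant_schedule(), 2019)

    def test_window_larger_than_span_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_schedule(self.constant_schedule(), 2030, window=21)

    def test_zero_parameter_falls_back_to_hold_last(self, caplog):
        years = np.arange(2000, 2010)
        sched = TransitionSchedule(years, np.zeros(10), np.full(10, 0.01), np.full(10, 0.3))
        with caplog.at_level("WARNING", logger="idmproj.calibration"):
            ext = extrapolate_schedule(sched, 2015, method="loglinear")
        assert np.all(ext.i == 0.0)
        assert "holding last" in caplog.text


class TestEpiSeriesValidation:
    def test_bounds_must_be_ordered(self):
        df = make_panel_frame([2000], [5], [1], [0.5], [900])
        df.loc[0, "lower"] = 10.0
        with pytest.raises(ValueError, match="bounds"):
            EpiSeries(df)

    def test_cause_deaths_without_prevalence_rejected(self):
        df = make_panel_frame([2000, 2001], [0, 0], [1, 1], [0.5, 0.5], [900, 900])
        with pytest.raises(InconsistentRatesError):
            EpiSeries(df)

    def test_keys_and_year_range(self, multikey_panel):
        assert len(multikey_panel.keys()) == 4
        for key in multikey_panel.keys():
            assert multikey_panel.year_range(key) == (1990, 2019)
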