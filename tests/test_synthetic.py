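"""Tests for the synthetic GBD-like panel generator."""

import numpy as np
import pytest

from idmproj.errors import AlignmentError, ConfigurationError
from idmproj.idm import TransitionSchedule, closed_form_constant_rates
from idmproj.synthetic import (
    GeneratorConfig,
    make_truth,
    observe,
    recovery_error,
    true_rate_panel,
)


class TestMakeTruth:
    def test_same_config_same_truth(self, constant_config):
        t1, t2 = make_truth(constant_config), make_truth(constant_config)
        assert t1.keys() == t2.keys()
        for key in t1.keys():
            assert t1.schedules[key] == t2.schedules[key]
            assert t1.initial_prevalence_per_100k[key] == t2.initial_prevalence_per_100k[key]

    def test_different_seeds_differ(self, constant_config):
        other = GeneratorConfig(**{**constant_config.__dict__, "seed": 8})
        key = ("Region A", "both")
        assert make_truth(other).schedules[key] != make_truth(constant_config).schedules[key]

    def test_zero_incidence_config(self):
        cfg = GeneratorConfig(n_locations=1, sexes=("both",), incidence_range=(0.0, 0.0), seed=1)
        truth = make_truth(cfg)
        for sched in truth.schedules.values():
            assert np.all(sched.i == 0.0)

    def test_constant_mode_reads_back_requested_constants(self):
        cfg = GeneratorConfig(
            n_locations=1,
            sexes=("both",),
            year_start=1990,
            year_end=2019,
            mode="constant",
            incidence_range=(1e-4, 1e-4),
            background_mortality_range=(1e-2, 1e-2),
            excess_mortality_range=(0.3, 0.3),
            seed=7,
        )
        sched = make_truth(cfg).schedules[("Region A", "both")]
        assert len(sched) == 30
        assert np.all(sched.i == 1e-4)
        assert np.all(sched.m_S == 1e-2)
        assert np.all(sched.m_I == 0.3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"incidence_range": (-0.1, 0.2)},
            {"excess_mortality_range": (0.5, 1.5)},
            {"year_start": 2020, "year_end": 2019},
            {"n_locations": 0},
            {"sexes": ("neuter",)},
            {"mode": "quadratic"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(seed=1, **kwargs)


class TestObserve:
    def test_noise_free_matches_closed_form(self, constant_truth, noisefree_panel):
        """With constant rates, emitted prevalence equals the analytic trajectory."""
        key = constant_truth.keys()[0]
        sched = constant_truth.schedules[key]
        init = constant_truth.initial_state(key)
        prev = noisefree_panel.observed_prevalence(key)
        for t, year in enumerate(range(constant_truth.year_start, constant_truth.year_end + 1)):
            S_t, I_t = closed_form_constant_rates(init.S, init.I, sched[year], t)
            assert prev.loc[year] == pytest.approx(1e5 * I_t / (S_t + I_t), rel=1e-12)

    def test_zero_noise_degenerate_bounds(self, noisefree_panel):
        df = noisefree_panel.frame
        assert (df["lower"] == df["value"]).all()
        assert (df["upper"] == df["value"]).all()

    def test_seeded_noise_is_reproducible(self, constant_truth):
        a = observe(constant_truth, noise_cv=0.05, seed=9)
        b = observe(constant_truth, noise_cv=0.05, seed=9)
        assert a.equals(b)
        c = observe(constant_truth, noise_cv=0.05, seed=10)
        assert not a.equals(c)

    def test_noise_mean_unbiased(self, constant_truth):
        """Mean of many noisy replicates of a cell sits near the clean value."""
        key = constant_truth.keys()[0]
        clean = true_rate_panel(constant_truth, key)
        target = clean.loc[clean["year"] == 2010, "prevalence"].item()
        cv = 0.1
        n = 1000
        vals = np.array(
            [
                observe(constant_truth, noise_cv=cv, seed=s)
                .observed_prevalence(key)
                .loc[2010]
                for s in range(n)
            ]
        )
        se = target * cv / np.sqrt(n)
        assert abs(vals.mean() - target) <= 3 * se

    def test_bounds_follow_lognormal_convention(self, constant_truth):
        panel = observe(constant_truth, noise_cv=0.05, seed=2)
        df = panel.frame
        sigma = np.sqrt(np.log1p(0.05**2))
        np.testing.assert_allclose(df["upper"], df["value"] * np.exp(1.96 * sigma), rtol=1e-12)
        np.testing.assert_allclose(df["lower"], df["value"] / np.exp(1.96 * sigma), rtol=1e-12)

    def test_negative_noise_cv_rejected(self, constant_truth):
        with pytest.raises(ConfigurationError):
            observe(constant_truth, noise_cv=-0.1)


class TestRecoveryError:
    def test_identity_gives_zero(self, constant_truth):
        summary = recovery_error(constant_truth, dict(constant_truth.schedules))
        assert summary.worst == 0.0
        assert all(v == 0.0 for v in summary.mean_abs.values())

    def test_single_cell_perturbation(self, constant_truth):
        key = constant_truth.keys()[0]
        sched = constant_truth.schedules[key]
        i = sched.i.copy()
        i[3] += 0.01
        perturbed = TransitionSchedule(sched.years, i, sched.m_S, sched.m_I)
        summary = recovery_error(constant_truth, {key: perturbed})
        assert summary.max_abs["i"] == pytest.approx(0.01, rel=1e-9)
        assert summary.mean_abs["i"] == pytest.approx(0.01 / len(sched), rel=1e-9)
        assert summary.max_abs["m_S"] == 0.0

    def test_key_mismatch_raises(self, constant_truth):
        with pytest.raises(AlignmentError):
            recovery_error(constant_truth, {})
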