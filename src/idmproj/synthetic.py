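"""Synthetic GBD-like rate panels from known illness-death dynamics.

The generator fabricates ground-truth transition schedules for a set of
(location, sex) keys, runs the illness-death model forward, and emits the
four observed measures — prevalence, incidence, cause-specific deaths and
all-cause deaths — as rates per 100,000 *total alive* population, matching
the denominator convention of GBD population rates. Because the emitted
rates use the same start-of-year denominators as the model step, the
calibration inversion recovers the generating schedule exactly in the
noise-free case; that round trip is the backbone of the test-suite.

Observation noise is multiplicative lognormal with mean 1 and a chosen
coefficient of variation, applied independently per cell; the emitted 95%
bounds are the noise law's 2.5/97.5 percentiles around the noisy value.
Defaults mimic a rare, highly lethal cancer in a standard population of
100,000: incidence of order 5 per 100,000, background mortality of order
900 per 100,000, annual case fatality 20-45%, initial prevalence a few per
100,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import Z95, sigma_from_cv
from .calibration import EpiSeries
from .errors import AlignmentError, ConfigurationError, DegenerateCohortError
from .idm import CohortState, TransitionSchedule, simulate

__all__ = ["GeneratorConfig", "SyntheticTruth", "make_truth", "observe", "recovery_error"]

_PARAMS = ("i", "m_S", "m_I")


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the synthetic-truth generator.

    Rate ranges are annual probabilities; each key draws its base value
    uniformly from the range. ``mode`` selects the temporal shape of every
    schedule: ``constant``; ``linear`` (value_t = v0 * (1 + a (t - t0)));
    or ``loglinear`` (value_t = v0 * exp(a (t - t0))), with the annual
    trend coefficient a drawn uniformly from ``trend_range``.
    """

    n_locations: int = 2
    sexes: Sequence[str] = ("male", "female", "both")
    year_start: int = 1990
    year_end: int = 2019
    mode: str = "constant"
    incidence_range: tuple[float, float] = (3e-5, 9e-5)
    background_mortality_range: tuple[float, float] = (6e-3, 1.2e-2)
    excess_mortality_range: tuple[float, float] = (0.2, 0.45)
    initial_prevalence_range: tuple[float, float] = (3.0, 7.0)  # per 100,000
    trend_range: tuple[float, float] = (-0.02, 0.02)
    cohort_size: float = 1e5
    entry_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 1:
            raise ConfigurationError("n_locations must be >= 1")
        if not self.sexes or set(self.sexes) - {"male", "female", "both"}:
            raise ConfigurationError("sexes must be a non-empty subset of {male, female, both}")
        if self.year_end < self.year_start:
            raise ConfigurationError("year range is empty")
        if self.mode not in ("constant", "linear", "loglinear"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        for name in ("incidence_range", "background_mortality_range", "excess_mortality_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"{name} must lie within [0, 1] with lo <= hi")
        lo, hi = self.initial_prevalence_range
        if not (0.0 <= lo <= hi < 1e5):
            raise ConfigurationError("initial_prevalence_range must lie within [0, 100000)")
        if self.cohort_size <= 0:
            raise ConfigurationError("cohort_size must be positive")
        if self.entry_rate < 0:
            raise ConfigurationError("entry_rate must be non-negative")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def locations(self) -> list[str]:
        return [f"Region {chr(ord('A') + k)}" for k in range(self.n_locations)]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth schedules and initial conditions behind a synthetic panel."""

    locations: tuple[str, ...]
    sexes: tuple[str, ...]
    year_start: int
    year_end: int
    schedules: Mapping[tuple[str, str], TransitionSchedule]
    initial_prevalence_per_100k: Mapping[tuple[str, str], float]
    cohort_size: float = 1e5
    entry_rate: float = 0.0
    config: GeneratorConfig | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        keys = {(loc, sex) for loc in self.locations for sex in self.sexes}
        if set(self.schedules) != keys or set(self.initial_prevalence_per_100k) != keys:
            raise ConfigurationError("schedules/initial prevalence must cover every (location, sex) key")
        for key, sched in self.schedules.items():
            if sched.start_year > self.year_start or sched.end_year < self.year_end:
                raise ConfigurationError(f"schedule for {key} does not cover the year range")
        for key, p0 in self.initial_prevalence_per_100k.items():
            if not 0.0 <= p0 < 1e5:
                raise ConfigurationError(f"initial prevalence for {key} outside [0, 100000)")

    def keys(self) -> list[tuple[str, str]]:
        return [(loc, sex) for loc in self.locations for sex in self.sexes]

    def initial_state(self, key: tuple[str, str]) -> CohortState:
        I0 = self.cohort_size * self.initial_prevalence_per_100k[key] / 1e5
        return CohortState(year=self.year_start, S=self.cohort_size - I0, I=I0, D=0.0)


def _shape(base: float, trend: float, rel_years: np.ndarray, mode: str) -> np.ndarray:
    if mode == "constant":
        vals = np.full(rel_years.size, base)
    elif mode == "linear":
        vals = base * (1.0 + trend * rel_years)
    else:  # loglinear
        vals = base * np.exp(trend * rel_years)
    return np.clip(vals, 0.0, 1.0)


def make_truth(config: GeneratorConfig) -> SyntheticTruth:
    """Draw a ground truth (schedules + initial conditions) from the config.

    Deterministic for a fixed config (the seed is part of the config);
    draw order is fixed by iterating locations then sexes.
    """
    rng = np.random.default_rng(config.seed)
    years = config.years
    rel = years - years[0]
    schedules: dict[tuple[str, str], TransitionSchedule] = {}
    p0s: dict[tuple[str, str], float] = {}
    for loc in config.locations:
        for sex in config.sexes:
            bases = {
                "i": rng.uniform(*config.incidence_range),
                "m_S": rng.uniform(*config.background_mortality_range),
                "m_I": rng.uniform(*config.excess_mortality_range),
            }
            trends = {p: rng.uniform(*config.trend_range) for p in _PARAMS}
            cols = {p: _shape(bases[p], trends[p], rel, config.mode) for p in _PARAMS}
            schedules[(loc, sex)] = TransitionSchedule(years, cols["i"], cols["m_S"], cols["m_I"])
            p0s[(loc, sex)] = rng.uniform(*config.initial_prevalence_range)
    return SyntheticTruth(
        locations=tuple(config.locations),
        sexes=tuple(config.sexes),
        year_start=config.year_start,
        year_end=config.year_end,
        schedules=schedules,
        initial_prevalence_per_100k=p0s,
        cohort_size=config.cohort_size,
        entry_rate=config.entry_rate,
        config=config,
    )


def true_rate_panel(truth: SyntheticTruth, key: tuple[str, str]) -> pd.DataFrame:
    """Noise-free observed measures for one key (rates per 100,000 alive).

    Runs the model across the truth's year range and emits, per year t,
    the four measures with start-of-year denominators:
    prevalence = I_t/(S_t+I_t); incidence = i_t S_t/(S_t+I_t);
    deaths_cause = m_I,t I_t/(S_t+I_t); deaths_all adds m_S,t S_t.
    """
    sched = truth.schedules[key]
    entry = {y: truth.entry_rate for y in range(truth.year_start, truth.year_end)}
    traj = simulate(truth.initial_state(key), sched, truth.year_end, entry_series=entry)
    S = np.array([s.S for s in traj])
    I = np.array([s.I for s in traj])
    alive = S + I
    if np.any(alive <= 0) or np.any(I / np.maximum(alive, 1e-300) >= 1.0):
        raise DegenerateCohortError(f"cohort for {key} became extinct or fully prevalent")
    years = traj.years
    k = years - sched.start_year
    i_t, mS_t, mI_t = sched.i[k], sched.m_S[k], sched.m_I[k]
    return pd.DataFrame(
        {
            "year": years,
            "prevalence": 1e5 * I / alive,
            "incidence": 1e5 * i_t * S / alive,
            "deaths_cause": 1e5 * mI_t * I / alive,
            "deaths_all": 1e5 * (mS_t * S + mI_t * I) / alive,
        }
    )


def observe(truth: SyntheticTruth, noise_cv: float = 0.0, seed: int | None = None) -> EpiSeries:
    """Emit the observed panel: model-implied rates with lognormal noise.

    Noise is multiplicative lognormal with mean 1 and coefficient of
    variation ``noise_cv``, independent per cell; bounds are the noise
    law's 2.5/97.5 percentiles around the emitted value. ``noise_cv = 0``
    gives lower == value == upper.
    """
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be non-negative")
    sigma = sigma_from_cv(noise_cv)
    rng = np.random.default_rng(seed)
    half_width = np.exp(Z95 * sigma)
    records = []
    for key in truth.keys():
        clean = true_rate_panel(truth, key)
        long = clean.melt(id_vars="year", var_name="measure", value_name="value")
        if sigma > 0:
            factors = np.exp(sigma * rng.standard_normal(len(long)) - 0.5 * sigma**2)
            long["value"] = long["value"] * factors
        long["lower"] = long["value"] / half_width
        long["upper"] = long["value"] * half_width
        long.insert(0, "location", key[0])
        long.insert(1, "sex", key[1])
        records.append(long)
    return EpiSeries(pd.concat(records, ignore_index=True))


@dataclass(frozen=True)
class RecoveryErrorSummary:
    """Absolute-error summary of estimated vs true schedules, per parameter."""

    max_abs: Mapping[str, float]
    mean_abs: Mapping[str, float]

    @property
    def worst(self) -> float:
        return max(self.max_abs.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"max_abs": self.max_abs, "mean_abs": self.mean_abs})


def recovery_error(
    truth: SyntheticTruth, estimated: Mapping[tuple[str, str], TransitionSchedule]
) -> RecoveryErrorSummary:
    """Compare estimated schedules with the generating truth.

    Both sides must carry the same keys; estimated schedules must cover
    the truth's year range (extra extrapolated years are ignored).
    """
    if set(estimated) != set(truth.keys()):
        raise AlignmentError(
            f"key mismatch: {sorted(set(estimated) ^ set(truth.keys()))}"
        )
    errs = {p: [] for p in _PARAMS}
    for key in truth.keys():
        true_s = truth.schedules[key]
        est_s = estimated[key]
        if est_s.start_year > truth.year_start or est_s.end_year < truth.year_end:
            raise AlignmentError(f"estimated schedule for {key} does not cover the truth years")
        sl_true = slice(truth.year_start - true_s.start_year, truth.year_end - true_s.start_year + 1)
        sl_est = slice(truth.year_start - est_s.start_year, truth.year_end - est_s.start_year + 1)
        for p in _PARAMS:
            diff = np.abs(getattr(est_s, p)[sl_est] - getattr(true_s, p)[sl_true])
            errs[p].append(diff)
    max_abs = {p: float(np.max(np.concatenate(v))) for p, v in errs.items()}
    mean_abs = {p: float(np.mean(np.concatenate(v))) for p, v in errs.items()}
    return RecoveryErrorSummary(max_abs=max_abs, mean_abs=mean_abs)
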