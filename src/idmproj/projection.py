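"""Forward projection of prevalence with Monte-Carlo uncertainty intervals.

For one (location, sex) key the pipeline is: calibrate an annual transition
schedule from the observed panel, extrapolate it to the horizon, build the
starting cohort from the last observed prevalence on a standard population
of 100,000, and iterate the illness-death step. The reported quantity is
prevalence per 100,000 alive (the model analogue of an age-standardized
prevalence rate), on the 5-year snapshot grid plus two period percentage
changes (observed history, and projection horizon).

Intervals come from parametric resampling: every observed rate is redrawn
from a lognormal whose 2.5/97.5 percentiles match its reported bounds, the
full calibrate -> extrapolate -> simulate pipeline is rerun per draw, and
the 2.5/97.5 empirical percentiles across draws form the interval. Draws
are independent across cells (no year-to-year correlation), which is the
simplest defensible propagation and stated as such. All draws for one call
are vectorised, so thousands of pipeline replicates cost one pass of the
annual loop on arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import sigma_from_bounds
from .calibration import MEASURES, EpiSeries, estimate_schedule, extrapolate_schedule
from .errors import ConfigurationError
from .idm import CohortState, TransitionSchedule, prevalence_per_100k, simulate

__all__ = ["ProjectionTable", "project", "monte_carlo_intervals"]


@dataclass(frozen=True)
class ProjectionTable:
    """Projected prevalence per 100,000 for one (location, sex) key.

    Years run from the last observed year (the projection anchor, whose
    value is the observed prevalence) to the horizon. ``pct_change_early``
    covers the observed period, ``pct_change_late`` the projection period.
    """

    location: str
    sex: str
    years: np.ndarray
    aspr: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    pct_change_early: float
    pct_change_late: float
    first_observed_year: int
    last_observed_year: int
    snapshot_years: np.ndarray

    def __post_init__(self) -> None:
        if not (self.years.shape == self.aspr.shape == self.lower.shape == self.upper.shape):
            raise ValueError("years/aspr/lower/upper must have equal length")
        if np.any(self.aspr < 0):
            raise ValueError("projected prevalence must be non-negative")
        if np.any(self.lower > self.upper):
            raise ValueError("interval bounds must be ordered")
        if not set(self.snapshot_years.tolist()) <= set(self.years.tolist()):
            raise ValueError("snapshot years must be a subset of projected years")

    @property
    def horizon_year(self) -> int:
        return int(self.years[-1])

    def at(self, year: int) -> tuple[float, float, float]:
        k = int(np.searchsorted(self.years, year))
        if k >= self.years.size or self.years[k] != year:
            raise KeyError(f"year {year} not in projection")
        return float(self.aspr[k]), float(self.lower[k]), float(self.upper[k])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long layout: one row per projected year plus the two periods."""
        rows = pd.DataFrame(
            {
                "location": self.location,
                "sex": self.sex,
                "year": self.years.astype(object),
                "estimate": self.aspr,
                "lower": self.lower,
                "upper": self.upper,
            }
        )
        periods = pd.DataFrame(
            {
                "location": self.location,
                "sex": self.sex,
                "year": [
                    f"{self.first_observed_year}-{self.last_observed_year}",
                    f"{self.last_observed_year}-{self.horizon_year}",
                ],
                "estimate": [self.pct_change_early, self.pct_change_late],
                "lower": [np.nan, np.nan],
                "upper": [np.nan, np.nan],
            }
        )
        return pd.concat([rows, periods], ignore_index=True)

    def snapshot_frame(self) -> pd.DataFrame:
        """One row with the 5-year snapshot columns and both period changes."""
        row: dict[str, object] = {"location": self.location, "sex": self.sex}
        for y in self.snapshot_years:
            est, lo, hi = self.at(int(y))
            row[f"aspr_{int(y)}"] = est
            row[f"lower_{int(y)}"] = lo
            row[f"upper_{int(y)}"] = hi
        row[f"pct_{self.first_observed_year}_{self.last_observed_year}"] = self.pct_change_early
        row[f"pct_{self.last_observed_year}_{self.horizon_year}"] = self.pct_change_late
        return pd.DataFrame([row])


def _snapshot_grid(last_observed: int, horizon: int) -> np.ndarray:
    return np.arange(last_observed + 1, horizon + 1, 5)


def _full_schedule(
    series: EpiSeries,
    key: tuple[str, str],
    horizon_year: int,
    method: str,
    window: int,
    annual_risk: str,
) -> TransitionSchedule:
    fitted = estimate_schedule(series, key, annual_risk=annual_risk)
    return extrapolate_schedule(fitted, horizon_year, method=method, window=window)


def project(
    series: EpiSeries,
    key: tuple[str, str],
    horizon_year: int,
    method: str = "loglinear",
    window: int = 10,
    cohort_size: float = 1e5,
    annual_risk: str = "identity",
) -> ProjectionTable:
    """Deterministic point projection for one key (zero-width intervals)."""
    first_obs, last_obs = series.year_range(key)
    if horizon_year <= last_obs:
        raise ValueError(f"horizon_year={horizon_year} must exceed last observed year {last_obs}")
    schedule = _full_schedule(series, key, horizon_year, method, window, annual_risk)
    obs_prev = series.observed_prevalence(key)
    I0 = cohort_size * float(obs_prev.loc[last_obs]) / 1e5
    initial = CohortState(year=last_obs, S=cohort_size - I0, I=I0, D=0.0)
    traj = simulate(initial, schedule, horizon_year)
    aspr = np.array([prevalence_per_100k(s) for s in traj])

    from .analytics import percentage_change  # local import avoids a cycle

    pct_early = percentage_change(float(obs_prev.loc[first_obs]), float(obs_prev.loc[last_obs]))
    pct_late = percentage_change(float(aspr[0]), float(aspr[-1]))
    return ProjectionTable(
        location=key[0],
        sex=key[1],
        years=traj.years,
        aspr=aspr,
        lower=aspr.copy(),
        upper=aspr.copy(),
        pct_change_early=pct_early,
        pct_change_late=pct_late,
        first_observed_year=first_obs,
        last_observed_year=last_obs,
        snapshot_years=_snapshot_grid(last_obs, horizon_year),
    )


def _draw_rates(
    values: np.ndarray, lowers: np.ndarray, uppers: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Resample observed rates: lognormal with 2.5/97.5 percentiles at the bounds."""
    sigma = sigma_from_bounds(lowers, uppers)
    median = np.where(sigma > 0, np.sqrt(lowers * uppers), values)
    z = rng.standard_normal((n_draws,) + values.shape)
    return median * np.exp(sigma * z)


def _vector_calibrate(draws: dict[str, np.ndarray], annual_risk: str) -> dict[str, np.ndarray]:
    """Rate -> probability inversion on (n_draws, n_years) arrays.

    Structural guards (cause <= all-cause, prevalence < 100%) are enforced
    by clipping rather than raising: independent resampling can produce
    rare inadmissible draws and a draw must never abort the whole ensemble.
    """
    p = np.minimum(draws["prevalence"] / 1e5, 1.0 - 1e-9)
    lam = draws["incidence"] / 1e5
    mu_a = draws["deaths_all"] / 1e5
    mu_c = np.minimum(draws["deaths_cause"] / 1e5, mu_a)
    one_minus_p = 1.0 - p
    i = lam / one_minus_p
    m_S = (mu_a - mu_c) / one_minus_p
    m_I = np.divide(mu_c, p, out=np.zeros_like(mu_c), where=p > 0)
    if annual_risk == "exponential":
        i, m_S, m_I = (1.0 - np.exp(-x) for x in (i, m_S, m_I))
    return {
        "i": np.clip(i, 0.0, 1.0),
        "m_S": np.clip(m_S, 0.0, 1.0),
        "m_I": np.clip(m_I, 0.0, 1.0),
    }


def _vector_extrapolate(
    params: dict[str, np.ndarray],
    obs_years: np.ndarray,
    horizon_year: int,
    method: str,
    window: int,
) -> dict[str, np.ndarray]:
    """Extend (n_draws, n_obs) parameter matrices to the horizon, per draw."""
    future = np.arange(obs_years[-1] + 1, horizon_year + 1)
    out: dict[str, np.ndarray] = {}
    for name, mat in params.items():
        last = mat[:, -1:]
        held = np.repeat(last, future.size, axis=1)
        if method == "hold_last" or future.size == 0:
            ext = held
        else:
            tail = mat[:, -window:]
            ok = np.all(tail > 0, axis=1)
            ext = held.copy()
            if ok.any():
                x = obs_years[-window:].astype(float)
                design = np.stack([x, np.ones_like(x)], axis=1)
                coef, *_ = np.linalg.lstsq(design, np.log(tail[ok]).T, rcond=None)
                slope, intercept = coef[0], coef[1]
                ext[ok] = np.exp(intercept[:, None] + slope[:, None] * future[None, :])
        out[name] = np.clip(np.concatenate([mat, ext], axis=1), 0.0, 1.0)
    excess = out["i"] + out["m_S"]
    scale = np.where(excess > 1.0, 1.0 / excess, 1.0)
    out["i"] = out["i"] * scale
    out["m_S"] = out["m_S"] * scale
    return out


def _vector_simulate_prevalence(
    p0: np.ndarray,
    sched: dict[str, np.ndarray],
    years: np.ndarray,
    last_obs: int,
    horizon_year: int,
    cohort_size: float,
) -> np.ndarray:
    """Iterate the IDM step on draw vectors; returns prevalence per 100k.

    ``sched`` arrays are (n_draws, n_years) aligned with ``years``; output
    is (n_draws, horizon_year - last_obs + 1).
    """
    I = cohort_size * np.clip(p0, 0.0, 1.0 - 1e-12)
    S = cohort_size - I
    prev = [1e5 * I / (S + I)]
    for year in range(last_obs, horizon_year):
        k = int(np.searchsorted(years, year))
        i_t, mS_t, mI_t = sched["i"][:, k], sched["m_S"][:, k], sched["m_I"][:, k]
        new_ill = i_t * S
        S = S - new_ill - mS_t * S
        I = I + new_ill - mI_t * I
        prev.append(1e5 * I / np.maximum(S + I, 1e-300))
    return np.stack(prev, axis=1)


def monte_carlo_intervals(
    series: EpiSeries,
    key: tuple[str, str],
    horizon_year: int,
    n_draws: int = 1000,
    seed: int | None = None,
    method: str = "loglinear",
    window: int = 10,
    cohort_size: float = 1e5,
    annual_risk: str = "identity",
) -> ProjectionTable:
    """Point projection plus empirical 95% intervals from resampled inputs.

    The point estimate is the no-noise run of :func:`project`; intervals
    are the 2.5/97.5 percentiles of the projected prevalence across
    ``n_draws`` full pipeline replicates. Deterministic for a fixed seed.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    point = project(
        series, key, horizon_year,
        method=method, window=window, cohort_size=cohort_size, annual_risk=annual_risk,
    )
    rng = np.random.default_rng(seed)
    values = {m: series.wide(key, "value")[m].to_numpy() for m in MEASURES}
    lowers = {m: series.wide(key, "lower")[m].to_numpy() for m in MEASURES}
    uppers = {m: series.wide(key, "upper")[m].to_numpy() for m in MEASURES}
    obs_years = series.wide(key).index.to_numpy()
    draws = {
        m: _draw_rates(values[m], lowers[m], uppers[m], n_draws, rng) for m in MEASURES
    }
    params = _vector_calibrate(draws, annual_risk)
    full = _vector_extrapolate(params, obs_years, horizon_year, method, window)
    all_years = np.arange(obs_years[0], horizon_year + 1)
    last_obs = int(obs_years[-1])
    p0 = draws["prevalence"][:, -1] / 1e5
    prev_paths = _vector_simulate_prevalence(
        p0, full, all_years, last_obs, horizon_year, cohort_size
    )
    if n_draws == 1:
        lower = upper = prev_paths[0]
    else:
        lower = np.percentile(prev_paths, 2.5, axis=0)
        upper = np.percentile(prev_paths, 97.5, axis=0)
    return ProjectionTable(
        location=point.location,
        sex=point.sex,
        years=point.years,
        aspr=point.aspr,
        lower=np.asarray(lower, dtype=float),
        upper=np.asarray(upper, dtype=float),
        pct_change_early=point.pct_change_early,
        pct_change_late=point.pct_change_late,
        first_observed_year=point.first_observed_year,
        last_observed_year=point.last_observed_year,
        snapshot_years=point.snapshot_years,
    )
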