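"""Calibration: observed rate panels -> annual transition probabilities.

GBD-style panels report, per (location, sex, year), four age-standardized
rates per 100,000 *total* population: prevalence, incidence, cause-specific
deaths and all-cause deaths. Writing p, lam, mu_c, mu_a for the same
quantities as proportions of the alive population, the per-compartment
annual transition probabilities of the illness-death model are

    i   = lam / (1 - p)            (incident cases arise from S)
    m_I = mu_c / p                 (prevalent-pool deaths arise from I)
    m_S = (mu_a - mu_c) / (1 - p)  (remaining deaths arise from S)

This inversion is exact against the discrete step equations when rates are
emitted with the same start-of-year denominators (see the synthetic
generator), which is what makes noise-free round-trip recovery a machine-
precision identity. Annual rates are treated directly as annual risks; an
actuarial ``1 - exp(-r)`` conversion is available as an option but changes
nothing at the rate magnitudes involved (1e-4 .. 1e-1 per year).
"""

from __future__ import annotations

import logging
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DegenerateCohortError,
    InconsistentRatesError,
    SchemaError,
)
from .idm import TransitionProbabilities, TransitionSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURES",
    "EpiSeries",
    "rates_to_probabilities",
    "estimate_schedule",
    "extrapolate_schedule",
]

#: the four panel measures, all rates per 100,000 total population
MEASURES = ("prevalence", "incidence", "deaths_cause", "deaths_all")

_COLUMNS = ["location", "sex", "measure", "year", "value", "lower", "upper"]

SEXES = ("male", "female", "both")


class EpiSeries:
    """Validated panel of observed rates per 100,000 with uncertainty bounds.

    Wraps a tidy DataFrame with columns ``location, sex, measure, year,
    value, lower, upper``. On construction the panel is checked for
    completeness: every (location, sex) key must carry all four measures
    over one contiguous year range, with ordered bounds and values in
    [0, 100000].
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"panel is missing columns: {missing}")
        df = frame.loc[:, _COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        for col in ("value", "lower", "upper"):
            df[col] = df[col].astype(float)
        bad_measure = set(df["measure"]) - set(MEASURES)
        if bad_measure:
            raise SchemaError(f"unknown measures: {sorted(bad_measure)}")
        if ((df["value"] < 0) | (df["value"] > 1e5)).any():
            raise ValueError("rate values must lie in [0, 100000]")
        if ((df["lower"] > df["value"]) | (df["value"] > df["upper"])).any():
            raise ValueError("bounds must satisfy lower <= value <= upper")
        df = df.sort_values(["location", "sex", "measure", "year"], kind="mergesort")
        df = df.reset_index(drop=True)
        self._frame = df
        self._validate_completeness()

    def _validate_completeness(self) -> None:
        for (loc, sex), sub in self._frame.groupby(["location", "sex"], sort=False):
            year_sets = {m: set(g["year"]) for m, g in sub.groupby("measure")}
            if set(year_sets) != set(MEASURES):
                missing = sorted(set(MEASURES) - set(year_sets))
                raise CoverageError(f"key ({loc}, {sex}) lacks measures {missing}")
            years = year_sets[MEASURES[0]]
            for m, ys in year_sets.items():
                if ys != years:
                    raise CoverageError(
                        f"key ({loc}, {sex}) measure {m} year mismatch: "
                        f"missing {sorted(years ^ ys)}"
                    )
            lo, hi = min(years), max(years)
            gaps = sorted(set(range(lo, hi + 1)) - years)
            if gaps:
                raise CoverageError(f"key ({loc}, {sex}) missing years {gaps}")
            dup = sub.duplicated(subset=["measure", "year"])
            if dup.any():
                raise ValueError(f"key ({loc}, {sex}) has duplicate (measure, year) rows")
            wide = self._wide(sub)
            prev_zero = wide["prevalence"] == 0
            if (prev_zero & (wide["deaths_cause"] > 0)).any():
                raise InconsistentRatesError(
                    f"key ({loc}, {sex}): cause-specific deaths with zero prevalence"
                )

    @staticmethod
    def _wide(sub: pd.DataFrame) -> pd.DataFrame:
        return sub.pivot(index="year", columns="measure", values="value")

    # -- accessors -----------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """The tidy panel (copy)."""
        return self._frame.copy()

    def keys(self) -> list[tuple[str, str]]:
        seen = self._frame[["location", "sex"]].drop_duplicates()
        return list(seen.itertuples(index=False, name=None))

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.keys())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in set(self.keys())

    def year_range(self, key: tuple[str, str]) -> tuple[int, int]:
        sub = self._subset(key)
        return int(sub["year"].min()), int(sub["year"].max())

    def _subset(self, key: tuple[str, str]) -> pd.DataFrame:
        loc, sex = key
        sub = self._frame[(self._frame["location"] == loc) & (self._frame["sex"] == sex)]
        if sub.empty:
            raise CoverageError(f"key {key} not present in panel")
        return sub

    def wide(self, key: tuple[str, str], field: str = "value") -> pd.DataFrame:
        """Year-indexed table with one column per measure for one key."""
        if field not in ("value", "lower", "upper"):
            raise ValueError("field must be value, lower or upper")
        sub = self._subset(key)
        return sub.pivot(index="year", columns="measure", values=field)[list(MEASURES)]

    def observed_prevalence(self, key: tuple[str, str]) -> pd.Series:
        return self.wide(key)["prevalence"]

    def equals(self, other: "EpiSeries") -> bool:
        return self._frame.equals(other._frame)

    def __len__(self) -> int:
        return len(self._frame)


def _as_proportions(prev, inc, mort_cause, mort_all):
    p = np.asarray(prev, dtype=float) / 1e5
    lam = np.asarray(inc, dtype=float) / 1e5
    mu_c = np.asarray(mort_cause, dtype=float) / 1e5
    mu_a = np.asarray(mort_all, dtype=float) / 1e5
    return p, lam, mu_c, mu_a


def _invert_rates(p, lam, mu_c, mu_a, annual_risk: str):
    """Vectorised core of the rate -> probability inversion."""
    if np.any(p >= 1.0):
        raise DegenerateCohortError("prevalence of 100,000 per 100,000: empty susceptible pool")
    if np.any(mu_c > mu_a * (1 + 1e-12)):
        raise InconsistentRatesError("cause-specific mortality exceeds all-cause mortality")
    if np.any((mu_c > 0) & (p <= 0)):
        raise InconsistentRatesError("cause-specific deaths observed with zero prevalence")
    one_minus_p = 1.0 - p
    i = lam / one_minus_p
    m_S = (mu_a - mu_c) / one_minus_p
    m_I = np.divide(mu_c, p, out=np.zeros_like(mu_c), where=p > 0)
    if annual_risk == "exponential":
        i, m_S, m_I = (1.0 - np.exp(-x) for x in (i, m_S, m_I))
    elif annual_risk != "identity":
        raise ValueError("annual_risk must be 'identity' or 'exponential'")
    clipped = np.clip(np.stack([i, m_S, m_I]), 0.0, 1.0)
    if not np.allclose(clipped, np.stack([i, m_S, m_I]), rtol=0, atol=0, equal_nan=True):
        n = int(np.sum(clipped != np.stack([i, m_S, m_I])))
        logger.warning("clamped %d transition probabilities into [0, 1]", n)
    return clipped[0], clipped[1], clipped[2]


def rates_to_probabilities(
    prev: float,
    inc: float,
    mort_cause: float,
    mort_all: float,
    annual_risk: str = "identity",
) -> TransitionProbabilities:
    """Convert one year's observed rates (per 100,000) into IDM probabilities."""
    p, lam, mu_c, mu_a = _as_proportions(prev, inc, mort_cause, mort_all)
    i, m_S, m_I = _invert_rates(p, lam, mu_c, mu_a, annual_risk)
    return TransitionProbabilities(float(i), float(m_S), float(m_I))


def estimate_schedule(
    series: EpiSeries,
    key: tuple[str, str],
    annual_risk: str = "identity",
) -> TransitionSchedule:
    """Per-year transition probabilities for one (location, sex) key.

    Applies :func:`rates_to_probabilities` to every observed year; the
    panel's completeness validation guarantees contiguous coverage.
    """
    wide = series.wide(key)
    p, lam, mu_c, mu_a = _as_proportions(
        wide["prevalence"].to_numpy(),
        wide["incidence"].to_numpy(),
        wide["deaths_cause"].to_numpy(),
        wide["deaths_all"].to_numpy(),
    )
    i, m_S, m_I = _invert_rates(p, lam, mu_c, mu_a, annual_risk)
    return TransitionSchedule(wide.index.to_numpy(), i, m_S, m_I)


def extrapolate_schedule(
    schedule: TransitionSchedule,
    end_year: int,
    method: str = "loglinear",
    window: int = 10,
) -> TransitionSchedule:
    """Extend a fitted schedule beyond its last observed year.

    ``hold_last`` repeats the final year's probabilities. ``loglinear`` fits
    a straight line to log(probability) over the trailing ``window`` years
    of each parameter and extends it, clamping into [0, 1]; a parameter with
    a non-positive value inside the window falls back to hold_last (logged),
    since its log-trend is undefined. Observed years are returned unchanged.
    """
    if end_year <= schedule.end_year:
        raise ValueError(
            f"end_year={end_year} must exceed last observed year {schedule.end_year}"
        )
    if method not in ("hold_last", "loglinear"):
        raise ValueError("method must be 'hold_last' or 'loglinear'")
    if window < 1:
        raise ValueError("window must be a positive integer")
    if window > len(schedule):
        raise ValueError(
            f"window={window} exceeds observed span of {len(schedule)} years"
        )

    future = np.arange(schedule.end_year + 1, end_year + 1)
    extended: dict[str, np.ndarray] = {}
    for name in ("i", "m_S", "m_I"):
        observed = getattr(schedule, name)
        if method == "hold_last":
            ext = np.full(future.size, observed[-1])
        else:
            tail = observed[-window:]
            tail_years = schedule.years[-window:]
            if np.any(tail <= 0):
                logger.warning(
                    "loglinear: non-positive %s in trailing window; holding last value",
                    name,
                )
                ext = np.full(future.size, observed[-1])
            else:
                slope, intercept = np.polyfit(tail_years, np.log(tail), 1)
                ext = np.exp(intercept + slope * future)
        extended[name] = np.clip(np.concatenate([observed, ext]), 0.0, 1.0)

    years = np.concatenate([schedule.years, future])
    # keep i + m_S admissible after independent extrapolation
    excess = extended["i"] + extended["m_S"]
    over = excess > 1.0
    if over.any():
        logger.warning("rescaled i + m_S to 1 in %d extrapolated years", int(over.sum()))
        scale = np.where(over, 1.0 / excess, 1.0)
        extended["i"] = extended["i"] * scale
        extended["m_S"] = extended["m_S"] * scale
    return TransitionSchedule(years, extended["i"], extended["m_S"], extended["m_I"])
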