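"""Scikit-learn-style front end to the calibrate-and-project pipeline.

``IllnessDeathForecaster`` treats calibration as ``fit`` (one transition
schedule per (location, sex) key in the observed panel) and projection as
``predict`` (prevalence per 100,000 to a horizon year, optionally with
Monte-Carlo 95% intervals). It follows the estimator contract —
``get_params``/``set_params``, fitted attributes with trailing
underscores, ``check_is_fitted``-compatible — so it clones and composes
with sklearn model-selection utilities, while the module-level functions
in :mod:`idmproj.calibration` and :mod:`idmproj.projection` remain the
low-level surface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .calibration import EpiSeries, estimate_schedule
from .projection import ProjectionTable, monte_carlo_intervals, project

__all__ = ["IllnessDeathForecaster"]


class IllnessDeathForecaster(BaseEstimator):
    """Forecast chronic-disease prevalence with a calibrated illness-death model.

    Parameters
    ----------
    method : {"loglinear", "hold_last"}
        Post-observation evolution of the transition probabilities:
        log-linear continuation of the trailing trend, or freezing the
        final observed year.
    window : int
        Trailing years used for the log-linear fit.
    cohort_size : float
        Standard population; 100,000 makes rates and counts coincide.
    annual_risk : {"identity", "exponential"}
        Whether annual rates are used directly as annual risks or passed
        through 1 - exp(-r).
    n_draws : int
        Monte-Carlo replicates behind 95% intervals.
    random_state : int or None
        Seed for the interval resampling.

    Attributes
    ----------
    schedules_ : dict[(location, sex), TransitionSchedule]
        Calibrated annual transition probabilities per key.
    keys_ : list[(location, sex)]
        Panel keys, in panel order.
    series_ : EpiSeries
        The validated observed panel the model was fitted on.
    last_observed_year_ : dict[(location, sex), int]
        Projection anchor per key.

    Examples
    --------
    >>> from idmproj.synthetic import GeneratorConfig, make_truth, observe
    >>> panel = observe(make_truth(GeneratorConfig(seed=3)), noise_cv=0.0)
    >>> fc = IllnessDeathForecaster(method="hold_last").fit(panel)
    >>> table = fc.predict(2040)  # tidy frame, all keys
    """

    def __init__(
        self,
        method: str = "loglinear",
        window: int = 10,
        cohort_size: float = 1e5,
        annual_risk: str = "identity",
        n_draws: int = 1000,
        random_state: int | None = None,
    ) -> None:
        self.method = method
        self.window = window
        self.cohort_size = cohort_size
        self.annual_risk = annual_risk
        self.n_draws = n_draws
        self.random_state = random_state

    def fit(self, X: EpiSeries | pd.DataFrame, y: None = None) -> "IllnessDeathForecaster":
        """Calibrate one transition schedule per (location, sex) key.

        ``X`` is an :class:`EpiSeries` or a tidy DataFrame with columns
        location, sex, measure, year, value, lower, upper. ``y`` is
        ignored (panel methods carry their target inside ``X``).
        """
        series = X if isinstance(X, EpiSeries) else EpiSeries(X)
        self.series_ = series
        self.keys_ = series.keys()
        self.schedules_ = {
            key: estimate_schedule(series, key, annual_risk=self.annual_risk)
            for key in self.keys_
        }
        self.last_observed_year_ = {key: series.year_range(key)[1] for key in self.keys_}
        return self

    def _check_horizon(self, horizon_year: int) -> None:
        check_is_fitted(self, "schedules_")
        latest = max(self.last_observed_year_.values())
        if horizon_year <= latest:
            raise ValueError(
                f"horizon_year={horizon_year} must exceed the last observed year {latest}"
            )

    def predict_table(
        self, horizon_year: int, key: tuple[str, str], with_intervals: bool = False
    ) -> ProjectionTable:
        """Full :class:`ProjectionTable` for a single key."""
        self._check_horizon(horizon_year)
        common = dict(
            method=self.method,
            window=self.window,
            cohort_size=self.cohort_size,
            annual_risk=self.annual_risk,
        )
        if not with_intervals:
            return project(self.series_, key, horizon_year, **common)
        seed = self._key_seed(key)
        return monte_carlo_intervals(
            self.series_, key, horizon_year, n_draws=self.n_draws, seed=seed, **common
        )

    def _key_seed(self, key: tuple[str, str]) -> int:
        """Stable per-key child seed so key order cannot leak randomness."""
        idx = self.keys_.index(key)
        child = np.random.SeedSequence(self.random_state, spawn_key=(idx,))
        return int(child.generate_state(1)[0] % (2**31))

    def predict(self, horizon_year: int, with_intervals: bool = False) -> pd.DataFrame:
        """Tidy projections for every fitted key up to ``horizon_year``."""
        self._check_horizon(horizon_year)
        frames = [
            self.predict_table(horizon_year, key, with_intervals=with_intervals).to_frame()
            for key in self.keys_
        ]
        return pd.concat(frames, ignore_index=True)

    def score(self, X: EpiSeries | pd.DataFrame, y: None = None) -> float:
        """Negative mean squared error of one-step-ahead prevalence (per 100k).

        Refits nothing: uses the fitted schedules to step each observed
        year forward and compares with the next observed prevalence in
        ``X``. Mainly useful for model selection over ``method``/``window``.
        """
        check_is_fitted(self, "schedules_")
        series = X if isinstance(X, EpiSeries) else EpiSeries(X)
        errs: list[float] = []
        for key in series.keys():
            if key not in self.schedules_:
                continue
            prev = series.observed_prevalence(key)
            sched = self.schedules_[key]
            for year in prev.index[:-1]:
                if year not in sched:
                    continue
                p = float(prev.loc[year]) / 1e5
                probs = sched[year]
                S, I = self.cohort_size * (1 - p), self.cohort_size * p
                S1 = S - probs.i * S - probs.m_S * S
                I1 = I + probs.i * S - probs.m_I * I
                pred = 1e5 * I1 / (S1 + I1)
                errs.append((pred - float(prev.loc[year + 1])) ** 2)
        if not errs:
            raise ValueError("no overlapping (key, year) pairs to score")
        return -float(np.mean(errs))
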