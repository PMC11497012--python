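"""Trend statistics derived from projection tables and region panels.

Covers the report-level quantities of a prevalence-forecasting study:
period percentage changes, geometric average annual percent change (AAPC),
female-vs-male excess of a percentage change, the fold-change between two
periods' percentage changes, extremum ranking across regions, and
threshold counts. Scalar operations work on plain floats; panel operations
take a region-indexed DataFrame (a *region panel*).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SchemaError
from .projection import ProjectionTable

logger = logging.getLogger(__name__)

__all__ = [
    "percentage_change",
    "aapc",
    "sex_excess",
    "period_fold_change",
    "SIGN_FLIP",
    "rank_extremum",
    "count_exceeding",
    "region_panel",
    "lollipop_long",
]


def percentage_change(v_start: float, v_end: float) -> float:
    """Percent change 100 * (v_end - v_start) / v_start over a period."""
    if v_start <= 0:
        raise ValueError(f"v_start must be positive, got {v_start!r}")
    return 100.0 * (v_end - v_start) / v_start


def aapc(
    values: Iterable[float],
    t0_index: int = 0,
    t1_index: int = -1,
    years: Iterable[int] | None = None,
) -> float:
    """Geometric average annual percent change between two series entries.

    100 * ((v_t1 / v_t0)^(1 / (t1 - t0)) - 1), the constant annual growth
    rate carrying v_t0 to v_t1. With ``years`` given, the elapsed time is
    years[t1] - years[t0] (so sparse snapshot grids work); otherwise the
    series is assumed annual and the index difference is used.
    """
    arr = np.asarray(list(values), dtype=float)
    if np.any(arr <= 0):
        raise ValueError("aapc requires a strictly positive series")
    t0 = t0_index if t0_index >= 0 else arr.size + t0_index
    t1 = t1_index if t1_index >= 0 else arr.size + t1_index
    if not 0 <= t0 < t1 < arr.size:
        raise ValueError(f"need 0 <= t0 < t1 within the series, got ({t0}, {t1})")
    if years is None:
        span = t1 - t0
    else:
        yrs = np.asarray(list(years), dtype=float)
        if yrs.shape != arr.shape:
            raise ValueError("years must align with values")
        span = yrs[t1] - yrs[t0]
        if span <= 0:
            raise ValueError("years must increase from t0 to t1")
    return 100.0 * ((arr[t1] / arr[t0]) ** (1.0 / span) - 1.0)


def sex_excess(pct_male: float, pct_female: float) -> float:
    """Excess of the female percentage change relative to the male one, in %."""
    if pct_male == 0:
        raise ValueError("male percentage change is zero; excess undefined")
    return 100.0 * (pct_female / pct_male - 1.0)


class _SignFlip:
    """Sentinel: the two periods' percentage changes have discordant signs."""

    _instance: "_SignFlip | None" = None

    def __new__(cls) -> "_SignFlip":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "SIGN_FLIP"


SIGN_FLIP = _SignFlip()


def period_fold_change(pct_early: float, pct_late: float):
    """Ratio pct_late / pct_early, or :data:`SIGN_FLIP` if pct_early <= 0.

    A ratio of sign-discordant (or zero-based) percentage changes has no
    meaningful magnitude, so such pairs are flagged rather than folded.
    """
    if pct_early <= 0:
        return SIGN_FLIP
    return pct_late / pct_early


def _require_column(panel: pd.DataFrame, column: str) -> pd.Series:
    if column not in panel.columns:
        raise SchemaError(f"panel has no column {column!r}; columns: {list(panel.columns)}")
    return panel[column]


def rank_extremum(panel: pd.DataFrame, column: str, mode: str = "max") -> tuple[str, float]:
    """Region achieving the max/min of a column, with its value.

    Ties are broken by lexicographically smallest region label (logged).
    """
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    if panel.empty:
        raise ValueError("panel is empty")
    col = _require_column(panel, column)
    target = col.max() if mode == "max" else col.min()
    winners = sorted(panel.index[col == target])
    if len(winners) > 1:
        logger.info("tie on %s %s among %s; reporting %s", mode, column, winners, winners[0])
    return str(winners[0]), float(target)


def count_exceeding(panel: pd.DataFrame, column: str, threshold: float) -> int:
    """Number of regions with column value strictly greater than threshold."""
    col = _require_column(panel, column)
    return int((col > threshold).sum())


def region_panel(tables: Iterable[ProjectionTable]) -> pd.DataFrame:
    """Assemble per-key projection tables into one region-indexed panel.

    One row per (location, sex); columns are the 5-year snapshot ASPRs
    plus the two period percentage changes, named as in
    :meth:`ProjectionTable.snapshot_frame`.
    """
    rows = [t.snapshot_frame() for t in tables]
    if not rows:
        return pd.DataFrame()
    panel = pd.concat(rows, ignore_index=True)
    dup = panel.duplicated(subset=["location", "sex"])
    if dup.any():
        raise ValueError("duplicate (location, sex) rows in region panel")
    return panel.set_index(["location", "sex"])


def lollipop_long(panel: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready long format of the two period changes per region/sex.

    Columns: location, sex, period, pct — one row per (region, sex,
    period), the layout a lollipop/dumbbell chart consumes.
    """
    pct_cols = [c for c in panel.columns if c.startswith("pct_")]
    if len(pct_cols) != 2:
        raise SchemaError(f"expected exactly two pct_* columns, found {pct_cols}")
    out = (
        panel[pct_cols]
        .reset_index()
        .melt(id_vars=["location", "sex"], var_name="period", value_name="pct")
    )
    out["period"] = out["period"].str.replace("pct_", "", regex=False).str.replace("_", "-")
    return out.sort_values(["location", "sex", "period"]).reset_index(drop=True)
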