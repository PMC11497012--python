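"""Shared numerical helpers for the lognormal uncertainty convention.

Observed rates are positive and their uncertainty skewed, so both the
synthetic generator and the Monte-Carlo propagation use a multiplicative
lognormal law. The 95% bounds convention is value */÷ exp(Z95 * sigma).
"""

from __future__ import annotations

import numpy as np

#: normal quantile used for 95% bounds throughout the package
Z95 = 1.96


def sigma_from_cv(cv: float) -> float:
    """Lognormal log-scale sigma with coefficient of variation ``cv``."""
    if cv < 0:
        raise ValueError("coefficient of variation must be non-negative")
    return float(np.sqrt(np.log1p(cv**2)))


def sigma_from_bounds(lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Log-scale sigma of a lognormal whose 2.5/97.5 percentiles are (lower, upper).

    Cells with a zero bound (point values, or rates observed as 0) get
    sigma 0, i.e. are treated as fixed.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sig = np.log(upper / lower) / (2.0 * Z95)
    return np.where((lower > 0) & (upper > 0), sig, 0.0)
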