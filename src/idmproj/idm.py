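"""Discrete-time illness-death model (IDM).

Three states: susceptible (S), ill (I) and an absorbing death state (D,
tracked as cumulative deaths). Each calendar year a susceptible individual
becomes ill with probability ``i`` or dies with probability ``m_S``; an ill
individual dies with probability ``m_I``. There is no remission. The annual
update is

    S_{t+1} = S_t - i_t S_t - m_S,t S_t (+ entry)
    I_{t+1} = I_t + i_t S_t - m_I,t I_t
    D_{t+1} = D_t + m_S,t S_t + m_I,t I_t

Propagation is deterministic (expected values, real-valued compartments);
for a closed cohort (entry = 0) S + I + D is conserved exactly.

The constant-rate recursion has a closed-form solution used as an
independent oracle in the test-suite: see
:func:`closed_form_constant_rates`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, DegenerateCohortError

__all__ = [
    "TransitionProbabilities",
    "TransitionSchedule",
    "CohortState",
    "Trajectory",
    "step",
    "simulate",
    "prevalence_per_100k",
    "closed_form_constant_rates",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class TransitionProbabilities:
    """Annual transition probabilities of the illness-death model.

    Parameters
    ----------
    i : float
        Probability susceptible -> ill within one year.
    m_S : float
        Probability susceptible -> dead within one year (background
        mortality of the disease-free population).
    m_I : float
        Probability ill -> dead within one year (mortality of the
        prevalent pool, all causes).
    """

    i: float
    m_S: float
    m_I: float

    def __post_init__(self) -> None:
        for name in ("i", "m_S", "m_I"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0 or v > 1.0:
                raise ValueError(f"{name}={v!r} is not a probability in [0, 1]")
        if self.i + self.m_S > 1.0 + _PROB_TOL:
            raise ValueError(
                f"total annual outflow from S exceeds 1: i + m_S = {self.i + self.m_S!r}"
            )


class TransitionSchedule:
    """Per-year transition probabilities over a contiguous span of years.

    Stored columnar (numpy arrays) so calibration and simulation can stay
    vectorised; item access by calendar year returns a
    :class:`TransitionProbabilities`.
    """

    def __init__(
        self,
        years: Sequence[int],
        i: Sequence[float],
        m_S: Sequence[float],
        m_I: Sequence[float],
    ) -> None:
        years_arr = np.asarray(years, dtype=int)
        if years_arr.size == 0:
            raise ValueError("schedule must cover at least one year")
        if not np.array_equal(np.diff(years_arr), np.ones(years_arr.size - 1, dtype=int)):
            raise ValueError("schedule years must be contiguous integers")
        self.years = years_arr
        self.i = np.asarray(i, dtype=float)
        self.m_S = np.asarray(m_S, dtype=float)
        self.m_I = np.asarray(m_I, dtype=float)
        if not (self.i.shape == self.m_S.shape == self.m_I.shape == years_arr.shape):
            raise ValueError("years, i, m_S, m_I must have equal length")
        for name, arr in (("i", self.i), ("m_S", self.m_S), ("m_I", self.m_I)):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
                raise ValueError(f"{name} contains values outside [0, 1]")
        if np.any(self.i + self.m_S > 1.0 + _PROB_TOL):
            raise ValueError("i + m_S exceeds 1 in at least one year")

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, TransitionProbabilities]) -> "TransitionSchedule":
        years = sorted(mapping)
        probs = [mapping[y] for y in years]
        return cls(years, [p.i for p in probs], [p.m_S for p in probs], [p.m_I for p in probs])

    @classmethod
    def constant(cls, probs: TransitionProbabilities, start_year: int, end_year: int) -> "TransitionSchedule":
        years = np.arange(start_year, end_year + 1)
        n = years.size
        return cls(years, np.full(n, probs.i), np.full(n, probs.m_S), np.full(n, probs.m_I))

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def __len__(self) -> int:
        return self.years.size

    def __contains__(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year

    def __getitem__(self, year: int) -> TransitionProbabilities:
        if year not in self:
            raise CoverageError(f"schedule does not cover year {year}")
        k = year - self.start_year
        return TransitionProbabilities(float(self.i[k]), float(self.m_S[k]), float(self.m_I[k]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionSchedule):
            return NotImplemented
        return (
            np.array_equal(self.years, other.years)
            and np.array_equal(self.i, other.i)
            and np.array_equal(self.m_S, other.m_S)
            and np.array_equal(self.m_I, other.m_I)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "i": self.i, "m_S": self.m_S, "m_I": self.m_I}
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TransitionSchedule({self.start_year}-{self.end_year}, "
            f"i~{self.i.mean():.3g}, m_S~{self.m_S.mean():.3g}, m_I~{self.m_I.mean():.3g})"
        )


@dataclass(frozen=True)
class CohortState:
    """Compartment occupancy of one cohort at the start of a calendar year."""

    year: int
    S: float
    I: float
    D: float = 0.0

    def __post_init__(self) -> None:
        if self.S < 0 or self.I < 0 or self.D < 0:
            raise ValueError(f"compartments must be non-negative: {self}")

    @property
    def alive(self) -> float:
        return self.S + self.I


@dataclass(frozen=True)
class Trajectory:
    """Annual sequence of cohort states, one per year, consecutive years."""

    states: tuple[CohortState, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        years = [s.year for s in self.states]
        if years and years != list(range(years[0], years[0] + len(years))):
            raise ValueError("trajectory years must increase by exactly 1")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterable[CohortState]:
        return iter(self.states)

    def __getitem__(self, idx: int) -> CohortState:
        return self.states[idx]

    def at(self, year: int) -> CohortState:
        first = self.states[0].year
        if not first <= year <= self.states[-1].year:
            raise CoverageError(f"trajectory does not cover year {year}")
        return self.states[year - first]

    @property
    def years(self) -> np.ndarray:
        return np.array([s.year for s in self.states])

    def prevalence_per_100k(self) -> np.ndarray:
        return np.array([prevalence_per_100k(s) for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": [s.year for s in self.states],
                "S": [s.S for s in self.states],
                "I": [s.I for s in self.states],
                "D": [s.D for s in self.states],
            }
        )


def step(state: CohortState, probs: TransitionProbabilities, entry: float = 0.0) -> CohortState:
    """Advance the cohort one year under the IDM update equations."""
    if entry < 0:
        raise ValueError("entry stream must be non-negative")
    new_ill = probs.i * state.S
    deaths_S = probs.m_S * state.S
    deaths_I = probs.m_I * state.I
    # max() guards against roundoff-negative occupancy at the i + m_S = 1
    # (or m_I = 1) boundary; the true values are non-negative by invariant
    return CohortState(
        year=state.year + 1,
        S=max(state.S - new_ill - deaths_S + entry, 0.0),
        I=max(state.I + new_ill - deaths_I, 0.0),
        D=state.D + deaths_S + deaths_I,
    )


def simulate(
    initial: CohortState,
    schedule: TransitionSchedule,
    end_year: int,
    entry_series: Mapping[int, float] | None = None,
) -> Trajectory:
    """Iterate :func:`step` from ``initial.year`` to ``end_year`` inclusive.

    ``schedule`` must cover every transition year, i.e. the interval
    ``[initial.year, end_year - 1]``. ``entry_series`` optionally maps a year
    to the number of new susceptibles entering during that year's step.
    """
    if end_year <= initial.year:
        raise ValueError(f"end_year={end_year} must exceed initial year {initial.year}")
    for year in (initial.year, end_year - 1):
        if year not in schedule:
            raise CoverageError(f"schedule does not cover transition year {year}")
    states = [initial]
    for year in range(initial.year, end_year):
        entry = float(entry_series.get(year, 0.0)) if entry_series else 0.0
        states.append(step(states[-1], schedule[year], entry))
    return Trajectory(tuple(states))


def prevalence_per_100k(state: CohortState) -> float:
    """Prevalence of the ill compartment as a rate per 100,000 alive."""
    alive = state.alive
    if alive == 0:
        raise DegenerateCohortError(f"cohort extinct at year {state.year}: S + I = 0")
    return 1e5 * state.I / alive


def closed_form_constant_rates(
    S0: float, I0: float, probs: TransitionProbabilities, t: int
) -> tuple[float, float]:
    """Closed-form (S_t, I_t) under constant transition probabilities.

    The S-recursion is geometric, S_t = S0 a^t with a = 1 - i - m_S. The
    I-recursion is a linear one-step recurrence whose solution is

        I_t = I0 b^t + i S0 (a^t - b^t) / (a - b),   b = 1 - m_I,

    with the a = b limit t i S0 a^(t-1) + I0 a^t. Used as the analytic
    oracle against which the iterated simulator is checked.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    a = 1.0 - probs.i - probs.m_S
    b = 1.0 - probs.m_I
    S_t = S0 * a**t
    if t == 0:
        return float(S0), float(I0)
    if abs(a - b) < 1e-14:
        geom = t * a ** (t - 1)
    else:
        geom = (a**t - b**t) / (a - b)
    I_t = I0 * b**t + probs.i * S0 * geom
    return float(S_t), float(I_t)
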