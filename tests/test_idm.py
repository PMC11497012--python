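"""Unit and property tests for the illness-death model core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idmproj.errors import CoverageError, DegenerateCohortError
from idmproj.idm import (
    CohortState,
    TransitionProbabilities,
    TransitionSchedule,
    closed_form_constant_rates,
    prevalence_per_100k,
    simulate,
    step,
)


def probs_strategy():
    """Valid transition probabilities with i + m_S <= 1."""
    return st.tuples(
        st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0)
    ).map(lambda t: TransitionProbabilities(t[0] * (1 - t[1]), t[1], t[2]))


class TestStep:
    @pytest.mark.parametrize(
        "state, probs, expected",
        [
            # all flows zero: identity
            ((1000, 50, 0), (0, 0, 0), (1000, 50, 0)),
            # one-year hand evaluation of the update equations
            ((100000, 100, 0), (5e-5, 1e-3, 0.12), (99895, 93, 112)),
            # total conversion of S into I in one year
            ((1000, 0, 0), (1, 0, 0), (0, 1000, 0)),
        ],
    )
    def test_hand_examples(self, state, probs, expected):
        out = step(CohortState(2000, *state), TransitionProbabilities(*probs))
        assert out.year == 2001
        assert (out.S, out.I, out.D) == pytest.approx(expected)

    def test_entry_stream_adds_to_susceptibles(self):
        out = step(CohortState(2000, 100.0, 10.0), TransitionProbabilities(0, 0, 0), entry=5.0)
        assert out.S == 105.0 and out.I == 10.0

    @given(probs=probs_strategy(), S=st.floats(0, 1e6), I=st.floats(0, 1e6), D=st.floats(0, 1e6))
    @settings(max_examples=200, derandomize=True)
    def test_conservation_and_nonnegativity(self, probs, S, I, D):
        out = step(CohortState(0, S, I, D), probs)
        assert out.S >= 0 and out.I >= 0 and out.D >= 0
        total0, total1 = S + I + D, out.S + out.I + out.D
        assert total1 == pytest.approx(total0, rel=1e-12, abs=1e-9)


class TestSimulate:
    def test_single_step_trajectory(self):
        probs = TransitionProbabilities(0.01, 0.01, 0.2)
        sched = TransitionSchedule.constant(probs, 2000, 2000)
        traj = simulate(CohortState(2000, 1000, 10), sched, 2001)
        assert len(traj) == 2
        assert traj[1] == step(traj[0], probs)

    def test_two_step_geometric_sum(self):
        sched = TransitionSchedule.constant(TransitionProbabilities(0.1, 0.1, 0.5), 0, 1)
        traj = simulate(CohortState(0, 1000, 0), sched, 2)
        assert traj[2].I == pytest.approx(130.0, rel=1e-12)
        assert traj[2].S == pytest.approx(640.0, rel=1e-12)

    def test_missing_schedule_year_raises(self):
        sched = TransitionSchedule.constant(TransitionProbabilities(0.1, 0.1, 0.5), 2000, 2005)
        with pytest.raises(CoverageError):
            simulate(CohortState(2000, 1000, 0), sched, 2010)

    def test_end_year_must_exceed_start(self):
        sched = TransitionSchedule.constant(TransitionProbabilities(0.1, 0.1, 0.5), 2000, 2005)
        with pytest.raises(ValueError):
            simulate(CohortState(2003, 1000, 0), sched, 2003)

    def test_conservation_along_random_schedule(self):
        rng = np.random.default_rng(5)
        years = np.arange(1990, 2030)
        i = rng.uniform(0, 0.3, years.size)
        m_S = rng.uniform(0, 0.3, years.size)
        m_I = rng.uniform(0, 0.9, years.size)
        sched = TransitionSchedule(years, i, m_S, m_I)
        traj = simulate(CohortState(1990, 9e4, 1e3, 2.0), sched, 2030)
        totals = [s.S + s.I + s.D for s in traj]
        assert np.max(np.abs(np.array(totals) / totals[0] - 1.0)) <= 1e-9

    def test_prevalence_monotone_in_single_year_incidence(self):
        """Raising one year's i never lowers prevalence at any later year."""
        rng = np.random.default_rng(17)
        years = np.arange(2000, 2020)
        base = TransitionSchedule(
            years,
            rng.uniform(0, 0.05, years.size),
            rng.uniform(0, 0.05, years.size),
            rng.uniform(0.1, 0.5, years.size),
        )
        bumped_i = base.i.copy()
        bumped_i[7] += 0.1
        bumped = TransitionSchedule(years, bumped_i, base.m_S, base.m_I)
        init = CohortState(2000, 99000, 1000)
        p_base = simulate(init, base, 2020).prevalence_per_100k()
        p_bump = simulate(init, bumped, 2020).prevalence_per_100k()
        assert np.all(p_bump >= p_base - 1e-12)

    def test_fixed_prevalence_symmetry(self):
        """With i = 0 and m_I = m_S both compartments shrink at the same rate."""
        sched = TransitionSchedule.constant(TransitionProbabilities(0.0, 0.07, 0.07), 0, 30)
        traj = simulate(CohortState(0, 5000.0, 250.0), sched, 30)
        p = traj.prevalence_per_100k()
        assert np.allclose(p, p[0], rtol=1e-12)


class TestPrevalence:
    @pytest.mark.parametrize(
        "S, I, expected", [(99900, 100, 100.0), (500, 0, 0.0), (0, 500, 100000.0)]
    )
    def test_direct_proportions(self, S, I, expected):
        assert prevalence_per_100k(CohortState(0, S, I)) == pytest.approx(expected)

    def test_extinct_cohort_raises(self):
        with pytest.raises(DegenerateCohortError):
            prevalence_per_100k(CohortState(0, 0, 0))


class TestClosedForm:
    def test_t_zero_is_initial_state(self):
        probs = TransitionProbabilities(0.2, 0.1, 0.4)
        assert closed_form_constant_rates(123.0, 45.0, probs, 0) == (123.0, 45.0)

    def test_hand_example(self):
        S2, I2 = closed_form_constant_rates(1000, 0, TransitionProbabilities(0.1, 0.1, 0.5), 2)
        assert S2 == pytest.approx(640.0, rel=1e-12)
        assert I2 == pytest.approx(130.0, rel=1e-12)

    def test_matches_iterated_step_randomized(self):
        """Oracle equivalence: closed form vs iteration, random probabilities."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            i, m_S = rng.uniform(0, 0.5), rng.uniform(0, 0.5)
            probs = TransitionProbabilities(i, m_S, rng.uniform(0, 1))
            S0, I0 = rng.uniform(1, 1e5), rng.uniform(0, 1e4)
            state = CohortState(0, S0, I0)
            for t in range(1, 51):
                state = step(state, probs)
                S_cf, I_cf = closed_form_constant_rates(S0, I0, probs, t)
                assert state.S == pytest.approx(S_cf, rel=1e-12, abs=1e-12)
                assert state.I == pytest.approx(I_cf, rel=1e-12, abs=1e-12)

    def test_equal_decay_rates_limit(self):
        probs = TransitionProbabilities(0.0, 0.3, 0.3)  # a == b branch
        state = CohortState(0, 1000.0, 100.0)
        for t in range(1, 20):
            state = step(state, probs)
        S_cf, I_cf = closed_form_constant_rates(1000.0, 100.0, probs, 19)
        assert (state.S, state.I) == pytest.approx((S_cf, I_cf), rel=1e-12)


class TestValidation:
    @pytest.mark.parametrize("bad", [(-0.1, 0, 0), (0, 1.2, 0), (0.7, 0.7, 0)])
    def test_invalid_probabilities_rejected(self, bad):
        with pytest.raises(ValueError):
            TransitionProbabilities(*bad)

    def test_schedule_requires_contiguous_years(self):
        with pytest.raises(ValueError):
            TransitionSchedule([2000, 2002], [0.1, 0.1], [0.1, 0.1], [0.1, 0.1])

    def test_schedule_lookup_outside_range(self):
        sched = TransitionSchedule.constant(TransitionProbabilities(0.1, 0.1, 0.1), 2000, 2001)
        with pytest.raises(CoverageError):
            sched[1999]

    def test_negative_compartments_rejected(self):
        with pytest.raises(ValueError):
            CohortState(0, -1.0, 0.0)
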