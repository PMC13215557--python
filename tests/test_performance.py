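"""Learning curve, experience factor, disposition, and partner selection."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from lunarbase.domain import AstronautState, RoverState, TaskSpec
from lunarbase.performance import (
    LearningCurve,
    attempt_task,
    disposition,
    learning_exponent,
    select_partner,
    technology_factor,
    unit_value,
)


def astronaut(aid=0, skills=None, coping=1.0, tension=0.0, personality="steady",
              n_rep=0, slope=0.85):
    return AstronautState(
        id=aid,
        skills=skills or {s: 0.5 for s in ("eva", "science", "engineering", "flightops")},
        personality_type=personality, habitat_assignment="moon_base",
        coping_capacity=coping, tension=tension,
        completed_repetitive_tasks=n_rep, learning_rate=slope)


class TestLearningExponent:
    @pytest.mark.parametrize("slope,expected", [
        (1.0, 0.0),
        (0.5, -1.0),
        (0.85, -0.23447),
    ])
    def test_values(self, slope, expected):
        assert learning_exponent(slope) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.01])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            learning_exponent(bad)


class TestUnitValue:
    @pytest.mark.parametrize("X,expected", [(1, 100.0), (2, 85.0), (4, 72.25)])
    def test_aerospace_slope(self, X, expected):
        curve = LearningCurve(A=100.0, slope=0.85)
        assert unit_value(curve, X) == pytest.approx(expected)

    def test_below_first_unit_rejected(self):
        with pytest.raises(ValueError):
            unit_value(LearningCurve(A=100.0, slope=0.85), 0)

    @settings(max_examples=60, derandomize=True)
    @given(slope=st.floats(0.01, 1.0), X=st.integers(1, 10**6))
    def test_doubling_halves_by_slope(self, slope, X):
        curve = LearningCurve(A=50.0, slope=slope)
        assert unit_value(curve, 2 * X) == pytest.approx(slope * unit_value(curve, X))


class TestTechnologyFactor:
    def test_zero_experience_is_base_level(self):
        assert technology_factor(0, 0.5, 0.85, 1.0) == 0.5

    def test_first_doubling_divides_by_slope(self):
        assert technology_factor(1, 0.5, 0.85, 1.0) == pytest.approx(0.5 / 0.85)

    def test_slope_one_means_no_learning(self):
        for n in (0, 5, 500):
            assert technology_factor(n, 0.7, 1.0, 1.0) == 0.7

    def test_reaches_cap_at_nineteen_repetitions_for_defaults(self):
        assert technology_factor(18, 0.5, 0.85, 1.0) < 1.0
        assert technology_factor(19, 0.5, 0.85, 1.0) == 1.0

    def test_monotone_in_experience_and_slope(self):
        values = [technology_factor(n, 0.5, 0.85, 1.0) for n in range(40)]
        assert values == sorted(values)
        by_slope = [technology_factor(6, 0.5, s, 1.0) for s in (0.75, 0.85, 0.95, 1.0)]
        assert by_slope == sorted(by_slope, reverse=True)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            technology_factor(1, 0.0, 0.85, 1.0)
        with pytest.raises(ValueError):
            technology_factor(-1, 0.5, 0.85, 1.0)


class TestDisposition:
    def test_solo(self):
        assert disposition(0.9, 0.2, 0.5) == pytest.approx(0.36)

    def test_pair_with_no_penalty(self):
        assert disposition(0.6, 0.0, 1.0, 0.4, 0.0) == pytest.approx(1.0)

    def test_total_penalty_annihilates(self):
        assert disposition(0.9, 1.0, 1.0, 0.8, 1.0) == 0.0

    @settings(max_examples=60, derandomize=True)
    @given(s=st.floats(0, 1), e1=st.floats(0, 1), e2=st.floats(0, 1), T=st.floats(0.1, 1))
    def test_monotone_decreasing_in_penalty(self, s, e1, e2, T):
        lo, hi = sorted((e1, e2))
        assert disposition(s, hi, T) <= disposition(s, lo, T)


class TestAttemptTask:
    def test_threshold_comparison_including_tie(self):
        # perfect psychology: E=0, non-repetitive -> D = skill
        skills = {"science": 0.36, "eva": 0, "engineering": 0, "flightops": 0}
        assert attempt_task(TaskSpec("science", 0.30), astronaut(skills=dict(skills))) is True
        assert attempt_task(TaskSpec("science", 0.50), astronaut(skills=dict(skills))) is False
        assert attempt_task(TaskSpec("science", 0.36), astronaut(skills=dict(skills))) is True  # tie

    def test_experience_factor_only_for_repetitive_types(self):
        skills = {"science": 0.6, "engineering": 0.6, "eva": 0.6, "flightops": 0.6}
        fresh = astronaut(skills=dict(skills))
        # repetitive task at zero experience: D = 0.6 * 0.5 = 0.30 < 0.4
        assert attempt_task(TaskSpec("maintenance", 0.40), fresh) is False
        # same threshold on a non-repetitive type succeeds (T = 1)
        fresh2 = astronaut(skills=dict(skills))
        assert attempt_task(TaskSpec("science", 0.40), fresh2) is True

    def test_rover_has_no_affect_or_learning(self):
        r = RoverState(id=9, skills={"exploration": 0.7, "infrastructure": 0.2,
                                     "engineering": 0.5}, position=(0, 0))
        assert attempt_task(TaskSpec("exploration", 0.65, agent_type="rover"), r) is True
        assert attempt_task(TaskSpec("infrastructure", 0.65, agent_type="rover"), r) is False

    def test_agent_type_mismatch_rejected(self):
        r = RoverState(id=9, skills={"exploration": 0.7, "infrastructure": 0.2,
                                     "engineering": 0.5}, position=(0, 0))
        with pytest.raises(ValueError):
            attempt_task(TaskSpec("mission_planning", 0.2), r)
        with pytest.raises(ValueError):
            attempt_task(TaskSpec("infrastructure", 0.2), astronaut())


class TestSelectPartner:
    def test_solo_sufficiency_needs_no_partner(self):
        a = astronaut(skills={"science": 0.8, "eva": 0, "engineering": 0, "flightops": 0})
        helper = astronaut(aid=1)
        assert select_partner(TaskSpec("science", 0.5), a, [helper]) is None

    def test_argmax_over_joint_disposition(self):
        worker = astronaut(aid=0, skills={"science": 0.3, "eva": 0, "engineering": 0,
                                          "flightops": 0})
        weak = astronaut(aid=1, skills={"science": 0.25, "eva": 0, "engineering": 0,
                                        "flightops": 0})
        strong = astronaut(aid=2, skills={"science": 0.40, "eva": 0, "engineering": 0,
                                          "flightops": 0})
        chosen = select_partner(TaskSpec("science", 0.6), worker, [weak, strong])
        assert chosen is strong

    def test_tie_prefers_compatible_personality(self):
        worker = astronaut(aid=0, personality="dominant",
                           skills={"science": 0.3, "eva": 0, "engineering": 0, "flightops": 0})
        same = {"science": 0.4, "eva": 0, "engineering": 0, "flightops": 0}
        neutral = astronaut(aid=1, personality="dominant", skills=dict(same))
        compatible = astronaut(aid=2, personality="conscientious", skills=dict(same))
        chosen = select_partner(TaskSpec("science", 0.9), worker, [neutral, compatible])
        assert chosen is compatible

    def test_remaining_tie_prefers_lowest_id(self):
        worker = astronaut(aid=5, personality="steady",
                           skills={"science": 0.3, "eva": 0, "engineering": 0, "flightops": 0})
        same = {"science": 0.4, "eva": 0, "engineering": 0, "flightops": 0}
        c1 = astronaut(aid=1, personality="steady", skills=dict(same))
        c2 = astronaut(aid=2, personality="steady", skills=dict(same))
        assert select_partner(TaskSpec("science", 0.9), worker, [c2, c1]) is c1

    def test_empty_candidates(self):
        a = astronaut()
        assert select_partner(TaskSpec("science", 0.9), a, []) is None
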