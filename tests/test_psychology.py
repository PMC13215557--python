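"""Coping/tension dynamics: pair rules, stressors, penalties, recovery."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from lunarbase.domain import AstronautState, PERSONALITIES, PsychParams
from lunarbase.psychology import (
    apply_stressor,
    apply_task_outcome,
    emotional_penalty,
    nightly_recovery,
    pair_adjustment,
)


def astronaut(coping=1.0, tension=0.0, personality="steady"):
    return AstronautState(id=0, skills={"engineering": 0.5},
                          personality_type=personality,
                          habitat_assignment="moon_base",
                          coping_capacity=coping, tension=tension)


EXPECTED_PAIRS = {
    frozenset({"dominant", "steady"}): (-0.05, 0.05),
    frozenset({"influential", "conscientious"}): (-0.05, 0.05),
    frozenset({"dominant", "conscientious"}): (0.05, -0.05),
    frozenset({"influential", "steady"}): (0.05, -0.05),
}


class TestPairAdjustment:
    def test_all_sixteen_ordered_pairs(self):
        for p, q in itertools.product(PERSONALITIES, repeat=2):
            expected = EXPECTED_PAIRS.get(frozenset({p, q}), (0.0, 0.0))
            assert pair_adjustment(p, q) == expected

    def test_symmetry(self):
        for p, q in itertools.product(PERSONALITIES, repeat=2):
            assert pair_adjustment(p, q) == pair_adjustment(q, p)

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError):
            pair_adjustment("dominant", "introvert")


class TestStressor:
    @pytest.mark.parametrize("before,after", [(0.70, 0.65), (0.03, 0.0), (0.0, 0.0)])
    def test_reduction_clamped_at_floor(self, before, after):
        a = astronaut(coping=before)
        apply_stressor(a)
        assert a.coping_capacity == pytest.approx(after)


class TestEmotionalPenalty:
    @pytest.mark.parametrize("coping,tension,expected", [
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 1.0),
        (0.6, 0.4, 0.4),
    ])
    def test_equal_weighting(self, coping, tension, expected):
        assert emotional_penalty(coping, tension) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            emotional_penalty(1.2, 0.0)
        with pytest.raises(ValueError):
            emotional_penalty(0.5, -0.1)

    @settings(max_examples=60, derandomize=True)
    @given(c1=st.floats(0, 1), c2=st.floats(0, 1), t=st.floats(0, 1))
    def test_monotone_nonincreasing_in_coping(self, c1, c2, t):
        lo, hi = sorted((c1, c2))
        assert emotional_penalty(hi, t) <= emotional_penalty(lo, t)

    @settings(max_examples=60, derandomize=True)
    @given(c=st.floats(0, 1), t1=st.floats(0, 1), t2=st.floats(0, 1))
    def test_monotone_nondecreasing_in_tension(self, c, t1, t2):
        lo, hi = sorted((t1, t2))
        assert emotional_penalty(c, hi) >= emotional_penalty(c, lo)


class TestTaskOutcome:
    def test_solo_failure_increments_tension(self):
        a = astronaut(tension=0.30)
        constants = PsychParams(failure_tension_delta=0.01)
        apply_task_outcome(a, None, success=False, task_type="science",
                          constants=constants)
        assert a.tension == pytest.approx(0.31)

    def test_compatible_pair_bonus_applies_on_any_outcome(self):
        w = astronaut(coping=0.5, tension=0.5, personality="dominant")
        p = astronaut(coping=0.5, tension=0.5, personality="conscientious")
        apply_task_outcome(w, p, success=True, task_type="science")
        assert w.coping_capacity == pytest.approx(0.55)
        assert p.coping_capacity == pytest.approx(0.55)
        assert w.tension == pytest.approx(0.45)
        assert p.tension == pytest.approx(0.45)

    def test_tension_clamped_at_zero_for_compatible_pair(self):
        w = astronaut(tension=0.0, personality="influential")
        p = astronaut(tension=0.0, personality="steady")
        apply_task_outcome(w, p, success=True, task_type="science")
        assert w.tension == 0.0 and p.tension == 0.0

    def test_repetitive_success_advances_experience(self):
        a = astronaut()
        apply_task_outcome(a, None, success=True, task_type="maintenance")
        assert a.completed_repetitive_tasks == 1
        apply_task_outcome(a, None, success=True, task_type="science")
        assert a.completed_repetitive_tasks == 1  # non-repetitive
        apply_task_outcome(a, None, success=False, task_type="maintenance")
        assert a.completed_repetitive_tasks == 1  # failure earns nothing


class TestNightlyRecovery:
    def test_coping_gain_and_tension_decay(self):
        a = astronaut(coping=0.60, tension=0.50)
        constants = PsychParams(recovery_coping_per_day=0.04,
                                tension_nightly_decay_factor=0.90)
        nightly_recovery(a, constants)
        assert a.coping_capacity == pytest.approx(0.64)
        assert a.tension == pytest.approx(0.45)

    def test_coping_clamped_at_ceiling(self):
        a = astronaut(coping=0.99)
        nightly_recovery(a, PsychParams(recovery_coping_per_day=0.04))
        assert a.coping_capacity == 1.0


class TestInvariants:
    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["stressor", "fail", "pair", "recover"]),
                              st.sampled_from(PERSONALITIES)),
                    min_size=0, max_size=80))
    def test_coping_and_tension_stay_in_unit_interval(self, events):
        a = astronaut(personality="dominant")
        for kind, partner_type in events:
            if kind == "stressor":
                apply_stressor(a)
            elif kind == "fail":
                apply_task_outcome(a, None, success=False, task_type="assembly")
            elif kind == "pair":
                p = astronaut(personality=partner_type)
                apply_task_outcome(a, p, success=True, task_type="science")
            else:
                nightly_recovery(a)
            assert 0.0 <= a.coping_capacity <= 1.0
            assert 0.0 <= a.tension <= 1.0

    def test_quiet_mission_converges_to_perfect_state(self):
        a = astronaut(coping=0.2, tension=0.9)
        prev_c, prev_t = a.coping_capacity, a.tension
        for _ in range(300):
            nightly_recovery(a)
            assert a.coping_capacity >= prev_c
            assert a.tension <= prev_t
            prev_c, prev_t = a.coping_capacity, a.tension
        assert a.coping_capacity == 1.0
        assert a.tension == pytest.approx(0.0, abs=1e-9)
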