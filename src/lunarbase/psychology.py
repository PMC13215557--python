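"""Coping-capacity and tension dynamics.

Two scalars on [0, 1] summarize each astronaut's psychological state:
coping capacity (personal: mood, motivation, morale; starts at 1.0) and
tension (interpersonal strain; starts at 0.0).  They move through four
mechanisms:

* DISC pair compatibility — when two astronauts jointly attempt a task,
  clashing style pairs (dominant–steady, influential–conscientious) cost
  0.05 coping and add 0.05 tension to both; complementary pairs
  (dominant–conscientious, influential–steady) give the mirror bonus.
  Unlisted pairs, including same-type pairs, are neutral.
* Stressors — every unexpected event or environmental shock costs 0.05
  coping.
* Task failures — each failed attempt adds a small tension increment to all
  participants.
* Nightly recovery — sleep restores some coping and decays tension
  multiplicatively.

Both scalars are clamped to [0, 1] after every update.  The emotional
penalty E = w_c (1 - coping) + w_t tension (equal weights by default) is the
affect factor that multiplies skill in the task disposition.
"""

from __future__ import annotations

from typing import Optional, Tuple

from lunarbase.domain import AstronautState, PERSONALITIES, PsychParams, REPETITIVE_TYPES

__all__ = [
    "pair_adjustment",
    "apply_stressor",
    "emotional_penalty",
    "apply_task_outcome",
    "nightly_recovery",
    "COMPATIBLE_PAIRS",
    "INCOMPATIBLE_PAIRS",
]

#: Unordered DISC pairs that work well together / clash.
COMPATIBLE_PAIRS = frozenset({
    frozenset({"dominant", "conscientious"}),
    frozenset({"influential", "steady"}),
})
INCOMPATIBLE_PAIRS = frozenset({
    frozenset({"dominant", "steady"}),
    frozenset({"influential", "conscientious"}),
})


def _clamp(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def _check_personality(p: str) -> None:
    if p not in PERSONALITIES:
        raise ValueError(f"invalid DISC personality {p!r}")


def pair_adjustment(p1: str, p2: str, delta: float = 0.05) -> Tuple[float, float]:
    """(coping delta, tension delta) for one jointly attempted task.

    Symmetric in its arguments; clashing pairs return ``(-delta, +delta)``,
    complementary pairs ``(+delta, -delta)``, everything else ``(0, 0)``.
    """
    _check_personality(p1)
    _check_personality(p2)
    pair = frozenset({p1, p2})
    if pair in INCOMPATIBLE_PAIRS:
        return (-delta, delta)
    if pair in COMPATIBLE_PAIRS:
        return (delta, -delta)
    return (0.0, 0.0)


def apply_stressor(a: AstronautState, constants: Optional[PsychParams] = None) -> AstronautState:
    """Apply one unexpected-event/environmental stressor: -0.05 coping (clamped)."""
    delta = (constants or PsychParams()).stressor_delta
    a.coping_capacity = _clamp(a.coping_capacity - delta)
    return a


def emotional_penalty(coping: float, tension: float,
                      constants: Optional[PsychParams] = None) -> float:
    """Affect penalty E in [0, 1]: equally weighted coping deficit and tension."""
    if not (0.0 <= coping <= 1.0 and 0.0 <= tension <= 1.0):
        raise ValueError("coping and tension must lie in [0, 1]")
    c = constants or PsychParams()
    return c.w_coping * (1.0 - coping) + c.w_tension * tension


def apply_task_outcome(worker: AstronautState, partner: Optional[AstronautState],
                       success: bool, task_type: str,
                       constants: Optional[PsychParams] = None) -> None:
    """Post-attempt bookkeeping for one task.

    Pair-compatibility deltas apply once per joint attempt regardless of the
    outcome; failures add the tension increment to every participant; a
    success on a repetitive task advances the worker's experience counter.
    """
    c = constants or PsychParams()
    if partner is not None:
        dc, dt = pair_adjustment(worker.personality_type, partner.personality_type,
                                 c.pair_delta)
        for a in (worker, partner):
            a.coping_capacity = _clamp(a.coping_capacity + dc)
            a.tension = _clamp(a.tension + dt)
    if not success:
        worker.tension = _clamp(worker.tension + c.failure_tension_delta)
        if partner is not None:
            partner.tension = _clamp(partner.tension + c.failure_tension_delta)
    elif task_type in REPETITIVE_TYPES:
        worker.completed_repetitive_tasks += 1


def nightly_recovery(a: AstronautState, constants: Optional[PsychParams] = None) -> AstronautState:
    """Overnight restoration: coping gains a fixed amount, tension decays."""
    c = constants or PsychParams()
    a.coping_capacity = _clamp(a.coping_capacity + c.recovery_coping_per_day)
    a.tension = _clamp(a.tension * c.tension_nightly_decay_factor)
    return a
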