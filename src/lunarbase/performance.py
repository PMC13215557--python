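"""Learning curve, experience factor, task disposition, and partner choice.

The learning curve follows the Wright unit-cost model Y = A X^b with
b = log(slope)/log 2: each doubling of cumulative repetitions multiplies the
unit cost by the slope.  Because the simulation tracks capability gained
rather than effort saved, the experience ("technology") factor is the
inverse curve, T(n) = min(Tmax, T0 (n+1)^(-b)), nondecreasing in the number
of completed repetitive tasks n and capped at Tmax.

Task success is decided by the disposition rule

    D = [S_i (1 - E_i) + S_j (1 - E_j)] * T

where S is the relevant professional skill, E the emotional penalty, and the
j-term appears only when a partner assists.  The experience factor T applies
only to the repetitive task types (assembly, maintenance, mission planning);
for all other types T = 1.  The task succeeds when D >= tau, where tau is
the task's cumulative skill requirement (ties count as success).  Rovers use
the same rule with no affect (E = 0) and no learning (T = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from lunarbase.domain import (
    AstronautState,
    PsychParams,
    RoverState,
    TaskSpec,
    REPETITIVE_TYPES,
    TASK_SKILL_MAP,
)
from lunarbase.psychology import (
    COMPATIBLE_PAIRS,
    apply_task_outcome,
    emotional_penalty,
)

__all__ = [
    "LearningCurve",
    "learning_exponent",
    "unit_value",
    "technology_factor",
    "disposition",
    "attempt_task",
    "select_partner",
]


def learning_exponent(slope: float) -> float:
    """Wright exponent b = log(slope)/log(2); 0 for slope 1, negative otherwise."""
    if not (0.0 < slope <= 1.0):
        raise ValueError("learning-curve slope must lie in (0, 1]")
    return math.log(slope) / math.log(2.0)


@dataclass(frozen=True)
class LearningCurve:
    """Unit-value curve Y = A X^b parameterized by first-unit value and slope."""

    A: float
    slope: float

    @property
    def b(self) -> float:
        return learning_exponent(self.slope)


def unit_value(curve: LearningCurve, X: float) -> float:
    """Unit value of the Xth repetition; halves by ``slope`` at each doubling."""
    if X < 1:
        raise ValueError("unit number X must be >= 1")
    return curve.A * X ** curve.b


def technology_factor(n_completed: int, T0: float, slope: float, Tmax: float) -> float:
    """Experience multiplier after ``n_completed`` repetitive-task successes.

    Inverse learning curve offset by one so it is defined at zero
    experience: T(n) = min(Tmax, T0 (n+1)^(-b)).
    """
    if n_completed < 0:
        raise ValueError("n_completed must be >= 0")
    if not (0.0 < T0 <= Tmax <= 1.0):
        raise ValueError("require 0 < T0 <= Tmax <= 1")
    b = learning_exponent(slope)
    return min(Tmax, T0 * (n_completed + 1) ** (-b))


def disposition(S_i: float, E_i: float, T: float,
                S_j: Optional[float] = None, E_j: Optional[float] = None) -> float:
    """Total disposition D; the partner term is included when S_j is given."""
    d = S_i * (1.0 - E_i)
    if S_j is not None:
        d += S_j * (1.0 - (E_j if E_j is not None else 0.0))
    return d * T


def _worker_T(worker: AstronautState, task_type: str,
              T0: float, Tmax: float) -> float:
    if task_type in REPETITIVE_TYPES:
        return technology_factor(worker.completed_repetitive_tasks, T0,
                                 worker.learning_rate, Tmax)
    return 1.0


def attempt_task(task: TaskSpec, worker, partner: Optional[AstronautState] = None,
                 constants: Optional[PsychParams] = None,
                 T0: float = 0.5, Tmax: float = 1.0) -> bool:
    """Resolve one task attempt and apply its psychological consequences.

    Raises ``ValueError`` if the worker's agent kind is not eligible for the
    task type per the task-skill mapping.
    """
    skill_key, agent_kinds = TASK_SKILL_MAP[task.task_type]
    if isinstance(worker, RoverState):
        if "rover" not in agent_kinds:
            raise ValueError(f"rovers cannot perform {task.task_type} tasks")
        key = "exploration" if task.task_type == "exploration" else skill_key
        success = disposition(worker.skills[key], 0.0, 1.0) >= task.tau
        return success
    if "astronaut" not in agent_kinds:
        raise ValueError(f"astronauts cannot perform {task.task_type} tasks")
    c = constants or PsychParams()
    T = _worker_T(worker, task.task_type, T0, Tmax)
    E_i = emotional_penalty(worker.coping_capacity, worker.tension, c)
    if partner is None:
        D = disposition(worker.skills[skill_key], E_i, T)
    else:
        E_j = emotional_penalty(partner.coping_capacity, partner.tension, c)
        D = disposition(worker.skills[skill_key], E_i, T,
                        partner.skills[skill_key], E_j)
    success = D >= task.tau
    apply_task_outcome(worker, partner, success, task.task_type, c)
    worker.technology_level = technology_factor(
        worker.completed_repetitive_tasks, T0, worker.learning_rate, Tmax)
    return success


def select_partner(task: TaskSpec, worker: AstronautState, candidates,
                   constants: Optional[PsychParams] = None,
                   T0: float = 0.5, Tmax: float = 1.0) -> Optional[AstronautState]:
    """Choose an assistant for ``task``, or ``None`` if the worker suffices.

    If the solo disposition already meets tau no partner is requested.
    Otherwise the candidate maximizing the joint disposition is picked;
    ties prefer a personality-compatible partner, then the lowest agent id.
    """
    c = constants or PsychParams()
    skill_key = TASK_SKILL_MAP[task.task_type][0]
    T = _worker_T(worker, task.task_type, T0, Tmax)
    E_i = emotional_penalty(worker.coping_capacity, worker.tension, c)
    if disposition(worker.skills[skill_key], E_i, T) >= task.tau:
        return None
    best = None
    best_key = None
    for cand in candidates:
        if cand is worker or not cand.alive:
            continue
        E_j = emotional_penalty(cand.coping_capacity, cand.tension, c)
        D = disposition(worker.skills[skill_key], E_i, T,
                        cand.skills[skill_key], E_j)
        compatible = frozenset({worker.personality_type,
                                cand.personality_type}) in COMPATIBLE_PAIRS
        key = (D, compatible, -cand.id)
        if best_key is None or key > best_key:
            best, best_key = cand, key
    return best
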