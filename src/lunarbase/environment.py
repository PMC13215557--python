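"""Exogenous events: hazard derivations, daily draws, equipment wear.

Daily event probabilities come from Poisson-process derivations over
observational rates: micrometeoroid impact gardening from the Lunar Orbiter
puncture rate (0.16 punctures/m^2/day over ~10 m^2 exposed, giving ~0.80 per
day), EVA-suit regolith wear from Apollo suit lifetimes (21-75 h of surface
life at 4 h daily exposure, giving 0.05-0.17 per day), solar particle events
from historical SPE frequency (0.005-0.024 per day), and moonquakes from the
Apollo seismic catalog.  Each triggered event stresses the crew of the
affected habitat and spawns an unexpected troubleshooting task.
"""

from __future__ import annotations

import math
from typing import List, Optional

import numpy as np

from lunarbase.domain import EventRates, HabitatState, TaskSpec, MOON_BASE

__all__ = [
    "poisson_at_least_one",
    "regolith_daily_probability",
    "draw_daily_events",
    "spawn_troubleshooting",
    "maintain_equipment",
    "consume_consumable",
    "SURFACE_ONLY_EVENTS",
]

#: Events tied to the lunar surface; the orbiting Gateway only experiences
#: radiation (solar particle events reach orbit) and unexpected tasks.
SURFACE_ONLY_EVENTS = ("impact", "regolith", "quake")


def poisson_at_least_one(rate_per_period: float) -> float:
    """P(at least one arrival in a period) = 1 - exp(-rate) under Poisson."""
    if rate_per_period < 0:
        raise ValueError("rate must be nonnegative")
    return 1.0 - math.exp(-rate_per_period)


def regolith_daily_probability(suit_life_hours: float,
                               exposure_hours_per_day: float) -> float:
    """Daily EVA-suit failure probability from abrasive regolith wear.

    Exponential failure with mean life ``suit_life_hours`` observed for
    ``exposure_hours_per_day`` hours: 1 - exp(-exposure/life).
    """
    if suit_life_hours <= 0 or exposure_hours_per_day <= 0:
        raise ValueError("suit life and exposure must be positive")
    return poisson_at_least_one(exposure_hours_per_day / suit_life_hours)


def draw_daily_events(rates: EventRates, rng: np.random.Generator,
                      surface: bool = True, eva_day: bool = True) -> List[str]:
    """Independent Bernoulli draw per event type; returns triggered names.

    Surface-only hazards are skipped for the orbital habitat; regolith wear
    is only drawn on days with EVA exposure.
    """
    events = []
    if rng.random() < rates.radiation_daily:
        events.append("radiation")
    if surface:
        if rng.random() < rates.impact_daily:
            events.append("impact")
        if eva_day and rng.random() < rates.regolith_daily:
            events.append("regolith")
        if rng.random() < rates.quake_daily:
            events.append("quake")
    if rng.random() < rates.unexpected_daily:
        events.append("unexpected")
    return events


def spawn_troubleshooting(event: str, rng: np.random.Generator,
                          scheduled_hour: int = 4) -> TaskSpec:
    """Unexpected troubleshooting task fixing the damage from ``event``."""
    unexpected_type = event if event in ("radiation", "impact", "quake") else "unexpected"
    return TaskSpec(
        task_type="troubleshooting",
        skill_1=float(rng.random()),
        skill_2=float(rng.random()),
        unexpected_type=unexpected_type,
        scheduled_hour=scheduled_hour,
    )


def consume_consumable(h: HabitatState, rng: np.random.Generator) -> Optional[TaskSpec]:
    """Spend one maintenance consumable; exhaustion spawns extra troubleshooting."""
    if h.equipment_consumables > 0:
        h.equipment_consumables -= 1
        return None
    return spawn_troubleshooting("unexpected", rng)


def maintain_equipment(h: HabitatState, rng: np.random.Generator) -> List[TaskSpec]:
    """Daily durable-equipment wear draw.

    With probability ``durables_daily`` one durable item is used up; demand
    against an exhausted stock spawns an unexpected troubleshooting task.
    """
    tasks: List[TaskSpec] = []
    if rng.random() < h.event_rates.durables_daily:
        if h.equipment_durables > 0:
            h.equipment_durables -= 1
        else:
            tasks.append(spawn_troubleshooting("unexpected", rng))
    return tasks
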