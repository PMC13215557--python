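"""Consumables, resupply flights, crew rotation, transfers, and deaths.

Each astronaut consumes 0.895 kg air, 5.03 kg water, and 2.39 kg food per
day; habitats start with a 180-day supply and receive a 30-day shipment per
crew member every resupply flight (default every 60 days / 1,440 h).  Each
flight carries an accident probability of 2/31 (two failures in 31
commercial resupply flights); a lost flight forfeits cargo and replacement
crew and stresses every survivor.  Crew rotation replaces a habitat's full
complement with fresh astronauts at the replacement cadence; the Moon lander
can optionally swap one astronaut between the habitats at a transfer
cadence.  A habitat whose stocks stay exhausted beyond a grace period
starves its crew; deaths remove the agent and stress the survivors.
"""

from __future__ import annotations

from typing import List

import numpy as np

from lunarbase.domain import (
    DAILY_AIR_KG,
    DAILY_FOOD_KG,
    DAILY_WATER_KG,
    GATEWAY,
    MOON_BASE,
    RESUPPLY_DAYS,
    HabitatState,
    ShuttleState,
    LanderState,
    WorldState,
    fresh_astronaut,
)
from lunarbase.psychology import apply_stressor

__all__ = [
    "consume_daily_resources",
    "produce_resources",
    "run_resupply",
    "transfer_crew",
    "remove_dead",
    "mass_balance",
    "DAILY_RATES",
]

DAILY_RATES = {"air": DAILY_AIR_KG, "water": DAILY_WATER_KG, "food": DAILY_FOOD_KG}


def consume_daily_resources(h: HabitatState, crew: list,
                            waste_fraction: float = 1.0,
                            grace_days: int = 3) -> None:
    """Daily life-support consumption for the habitat's living crew.

    Stocks floor at zero (the shortfall is a floor loss recorded implicitly
    by the ledger); any exhausted stock advances the starvation clock, and
    crew die once it exceeds the grace period.  Consumed food mass becomes
    waste.
    """
    living = [a for a in crew if a.alive]
    if not living:
        return
    n = len(living)
    starved = False
    for res, rate in DAILY_RATES.items():
        demand = n * rate
        stock = getattr(h, res)
        actual = min(stock, demand)
        setattr(h, res, stock - actual)
        h.ledger[res]["consumed"] += actual
        if stock - actual <= 0.0:
            starved = True
    h.waste += waste_fraction * n * DAILY_FOOD_KG
    if starved:
        h.starved_days += 1
        if h.starved_days > grace_days:
            for a in living:
                a.physical_health = 0.0
    else:
        h.starved_days = 0


def produce_resources(h: HabitatState, n_successes: int,
                      fraction: float = 0.25) -> None:
    """Credit successful hour-14 production work.

    Each success adds ``fraction`` of one astronaut-day of air, water, and
    food to the common reserves (storage is unbounded) and removes one
    astronaut-day of food waste (floored at zero).
    """
    if n_successes <= 0:
        return
    for res, rate in DAILY_RATES.items():
        amount = n_successes * fraction * rate
        setattr(h, res, getattr(h, res) + amount)
        h.ledger[res]["produced"] += amount
    h.waste = max(0.0, h.waste - n_successes * DAILY_FOOD_KG)


def _replace_crew(world: WorldState, kind: str) -> None:
    """Swap a habitat's full living complement for fresh astronauts."""
    outgoing = world.crew_of(kind)
    for a in outgoing:
        a.alive = False  # rotated home, not a death
        world.crew.remove(a)
    for _ in outgoing:
        world.crew.append(fresh_astronaut(world, kind))


def run_resupply(shuttle: ShuttleState, world: WorldState,
                 rng: np.random.Generator, hour: int) -> bool:
    """One shuttle flight: cargo drop plus any due crew replacement.

    Returns True if the flight succeeded.  On an accident the cargo and any
    replacement crew are lost and every surviving astronaut takes a
    stressor.
    """
    psych = world.config.psych
    if rng.random() < shuttle.accident_prob:
        for a in world.alive_crew:
            apply_stressor(a, psych)
        return False
    for kind in (MOON_BASE, GATEWAY):
        hab = world.habitat(kind)
        n = len(world.crew_of(kind))
        for res, rate in DAILY_RATES.items():
            amount = RESUPPLY_DAYS * n * rate
            setattr(hab, res, getattr(hab, res) + amount)
            hab.ledger[res]["shipped"] += amount
    if shuttle.base_replacement_frequency and hour % shuttle.base_replacement_frequency == 0:
        _replace_crew(world, MOON_BASE)
    if shuttle.gateway_replacement_frequency and hour % shuttle.gateway_replacement_frequency == 0:
        _replace_crew(world, GATEWAY)
    return True


def transfer_crew(lander: LanderState, world: WorldState) -> bool:
    """Swap one astronaut between Moon Base and Gateway (lowest-id pairing)."""
    base_crew = sorted(world.crew_of(MOON_BASE), key=lambda a: a.id)
    gw_crew = sorted(world.crew_of(GATEWAY), key=lambda a: a.id)
    if not base_crew or not gw_crew:
        return False
    down, up = base_crew[0], gw_crew[0]
    down.habitat_assignment, up.habitat_assignment = GATEWAY, MOON_BASE
    down.position = None
    up.position = world.base.position
    return True


def remove_dead(world: WorldState) -> int:
    """Remove dead astronauts and exhausted rovers; stress the survivors.

    Each death applies two stressors (bereavement) to every surviving
    astronaut.  Returns the number of astronaut deaths.
    """
    psych = world.config.psych
    dead = [a for a in world.crew if a.alive and a.physical_health <= 0.0]
    for a in dead:
        a.alive = False
        world.crew.remove(a)
        world.deaths += 1
        for survivor in world.alive_crew:
            apply_stressor(survivor, psych)
            apply_stressor(survivor, psych)
    for r in list(world.rovers):
        if r.energy <= 0.0:
            r.operational = False
            world.rovers.remove(r)
    return len(dead)


def mass_balance(h: HabitatState) -> dict:
    """Per-resource ledger check: initial + shipped + produced - consumed.

    Returns {resource: (expected_current, actual_current)}; the pair is
    equal up to floating-point rounding when the ledger is intact.
    """
    out = {}
    for res, entry in h.ledger.items():
        expected = entry["initial"] + entry["shipped"] + entry["produced"] - entry["consumed"]
        out[res] = (expected, getattr(h, res))
    return out
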