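"""World state types, scenario presets, and world construction.

Everything the simulation touches lives in the plain dataclasses defined
here: astronauts, rovers, the two habitats, the shuttle and lander, task
specifications, and the full scenario configuration.  ``initialize_world``
builds a reproducible initial world from a :class:`ScenarioConfig` and a
seed; ``make_scenario`` returns the named scenario presets used for the
comparison studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# Constants shared across modules

PERSONALITIES = ("dominant", "influential", "steady", "conscientious")

ASTRONAUT_SKILLS = ("eva", "science", "engineering", "flightops")
ROVER_SKILLS = ("infrastructure", "exploration", "engineering")

#: Task type -> (required skill, eligible agent kinds).  For exploration the
#: astronaut uses EVA skill while a rover uses its exploration skill.
TASK_SKILL_MAP = {
    "exploration": ("eva", ("astronaut", "rover")),
    "assembly": ("engineering", ("astronaut",)),
    "science": ("science", ("astronaut",)),
    "maintenance": ("engineering", ("astronaut",)),
    "troubleshooting": ("engineering", ("astronaut",)),
    "mission_planning": ("flightops", ("astronaut",)),
    "infrastructure": ("infrastructure", ("rover",)),
    # Hour-14 resource production is dispatched like a task (engineering
    # skill) but is not one of the seven numbered task types.
    "production": ("engineering", ("astronaut",)),
}

TASK_TYPE_CODES = {
    "exploration": 1,
    "assembly": 2,
    "science": 3,
    "maintenance": 4,
    "troubleshooting": 5,
    "mission_planning": 6,
    "infrastructure": 7,
}

#: Task types that benefit from the experience learning curve: the
#: repetitive, labor-intensive activities.
REPETITIVE_TYPES = frozenset({"assembly", "maintenance", "mission_planning"})

#: Daily per-astronaut consumption, kg/day (oxygen with contingency margin,
#: water, packaged food).
DAILY_AIR_KG = 0.895
DAILY_WATER_KG = 5.03
DAILY_FOOD_KG = 2.39

INITIAL_SUPPLY_DAYS = 180
RESUPPLY_DAYS = 30

#: Shuttle accident probability per flight: 2 failures in 31 commercial
#: resupply flights.
SHUTTLE_ACCIDENT_PROB = 2.0 / 31.0

MOON_BASE = "moon_base"
GATEWAY = "gateway"


class ConfigurationError(ValueError):
    """Raised when a scenario configuration violates an invariant."""


# ---------------------------------------------------------------------------
# Distributions for exogenous probabilities


@dataclass(frozen=True)
class Dist:
    """A scalar or a one-dimensional random distribution specification.

    ``kind`` is one of ``fixed``, ``uniform`` (lo, hi) or ``triangular``
    (lo, mode, hi) — the two families used for exogenous rates.
    """

    kind: str
    params: tuple

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return float(self.params[0])
        if self.kind == "uniform":
            lo, hi = self.params
            return float(rng.uniform(lo, hi))
        if self.kind == "triangular":
            lo, mode, hi = self.params
            return float(rng.triangular(lo, mode, hi))
        raise ConfigurationError(f"unknown distribution kind {self.kind!r}")

    def support(self) -> tuple:
        if self.kind == "fixed":
            return (self.params[0], self.params[0])
        return (self.params[0], self.params[-1])

    def to_spec(self):
        if self.kind == "fixed":
            return float(self.params[0])
        return {self.kind: list(self.params)}

    @staticmethod
    def from_spec(spec) -> "Dist":
        if isinstance(spec, Dist):
            return spec
        if isinstance(spec, (int, float)):
            return Dist("fixed", (float(spec),))
        if isinstance(spec, dict) and len(spec) == 1:
            kind, params = next(iter(spec.items()))
            return Dist(kind, tuple(float(p) for p in params))
        raise ConfigurationError(f"cannot parse distribution spec {spec!r}")


def fixed(x: float) -> Dist:
    return Dist("fixed", (float(x),))


# ---------------------------------------------------------------------------
# Agent state


@dataclass
class AstronautState:
    """One crew member.

    ``coping_capacity`` (personal psychological health) and ``tension``
    (interpersonal strain) both live in [0, 1] and drive the emotional
    penalty; ``skills`` holds one rating in [0, 1] per professional skill;
    ``completed_repetitive_tasks`` is the cumulative experience count feeding
    the learning curve.  Gateway-assigned astronauts carry no grid position.
    """

    id: int
    skills: dict
    personality_type: str
    habitat_assignment: str
    physical_health: float = 1.0
    coping_capacity: float = 1.0
    tension: float = 0.0
    mobility: int = 1
    position: Optional[tuple] = None
    carry_capacity: float = 10.0
    technology_level: float = 0.5
    learning_rate: float = 0.85
    completed_repetitive_tasks: int = 0
    alive: bool = True


@dataclass
class RoverState:
    """An autonomous surface rover (no affective state)."""

    id: int
    skills: dict
    position: tuple
    energy: float = 1.0
    mobility: int = 10
    cargo_capacity: float = 800.0
    operational: bool = True


@dataclass
class EventRates:
    """Realized daily event probabilities for one habitat."""

    radiation_daily: float = 0.012
    impact_daily: float = 0.80
    regolith_daily: float = 0.11
    quake_daily: float = 0.00096
    durables_daily: float = 0.00045
    unexpected_daily: float = 0.5


@dataclass
class HabitatState:
    """Moon Base or Gateway: resource stocks, equipment, event parameters.

    The ``ledger`` tracks, per resource, the initial stock and cumulative
    shipped / produced / consumed / removed masses so a mass-balance audit
    can be run at any time.
    """

    kind: str
    energy: float
    air: float
    water: float
    food: float
    waste: float = 0.0
    position: Optional[tuple] = None
    equipment_consumables: int = 100
    equipment_durables: int = 20
    event_rates: EventRates = field(default_factory=EventRates)
    starved_days: int = 0
    ledger: dict = field(default_factory=dict)

    def init_ledger(self) -> None:
        self.ledger = {
            res: {"initial": getattr(self, res), "shipped": 0.0,
                  "produced": 0.0, "consumed": 0.0}
            for res in ("air", "water", "food")
        }


@dataclass
class TaskSpec:
    """One task slot: type, random skill requirements, provenance.

    The task threshold tau is ``skill_1 + skill_2``; solo-only tasks carry
    ``skill_2 = 0``.  ``unexpected_type`` distinguishes scheduled work from
    unexpected tasks and from event-spawned troubleshooting.
    """

    task_type: str
    skill_1: float
    skill_2: float = 0.0
    agent_type: str = "astronaut"
    unexpected_type: str = "normal"
    scheduled_hour: int = 0

    @property
    def tau(self) -> float:
        return self.skill_1 + self.skill_2

    @property
    def required_skill(self) -> str:
        return TASK_SKILL_MAP[self.task_type][0]


@dataclass
class ShuttleState:
    energy: float = 4500.0
    shipment_frequency: int = 1440
    base_replacement_frequency: int = 1440
    gateway_replacement_frequency: int = 1440
    accident_prob: float = SHUTTLE_ACCIDENT_PROB


@dataclass
class LanderState:
    energy: float = 100.0
    transfer_frequency: int = 0  # 0 disables base<->gateway crew transfer


# ---------------------------------------------------------------------------
# Scenario configuration


@dataclass
class PsychParams:
    """Psychology constants (see the psychology module for semantics)."""

    pair_delta: float = 0.05
    stressor_delta: float = 0.05
    failure_tension_delta: float = 0.019
    recovery_coping_per_day: float = 0.06
    tension_nightly_decay_factor: float = 0.85
    w_coping: float = 0.5
    w_tension: float = 0.5


@dataclass
class TLXConfig:
    """Synthetic TLX composition weights and calibration targets.

    ``mu2``/``delta2`` default to the EDEN ISS greenhouse analog study
    (mean 60.0, SD 12.1), the calibration anchor for the baseline scenario.
    """

    w_tension: float = 1.0 / 3.0
    w_coping: float = 1.0 / 3.0
    w_tasks: float = 1.0 / 3.0
    mu2: float = 60.0
    delta2: float = 12.1


@dataclass
class ScenarioConfig:
    """Full parameterization of one simulation run."""

    name: str = "initial"
    n_astronauts: int = 4
    n_rovers: int = 2
    grid_side: int = 8          # square lattice, ~50 km^2 default
    duration_hours: int = 2016  # 3 months at 24 h/day
    learning_slope: float = 0.85
    technology_start: float = 0.5
    technology_max: float = 1.0
    shipment_frequency: int = 1440
    base_replacement_frequency: int = 1440
    gateway_replacement_frequency: int = 1440
    transfer_frequency: int = 0
    accident_prob: float = SHUTTLE_ACCIDENT_PROB
    radiation: Dist = field(default_factory=lambda: Dist("triangular", (0.005, 0.012, 0.024)))
    impact: Dist = field(default_factory=lambda: fixed(0.80))
    regolith: Dist = field(default_factory=lambda: Dist("uniform", (0.05, 0.17)))
    quake: Dist = field(default_factory=lambda: fixed(0.00096))
    durables: Dist = field(default_factory=lambda: Dist("uniform", (0.0001, 0.0008)))
    unexpected: Dist = field(default_factory=lambda: Dist("uniform", (0.0, 1.0)))
    production_fraction: float = 0.25
    waste_fraction: float = 1.0
    starvation_grace_days: int = 3
    scripted_death_hour: Optional[int] = None
    psych: PsychParams = field(default_factory=PsychParams)
    tlx: TLXConfig = field(default_factory=TLXConfig)
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_astronauts < 1:
            raise ConfigurationError("n_astronauts must be >= 1")
        if self.n_rovers < 0:
            raise ConfigurationError("n_rovers must be >= 0")
        if self.duration_hours < 24 or self.duration_hours % 24:
            raise ConfigurationError("duration_hours must be a positive multiple of 24")
        if not (0.0 < self.learning_slope <= 1.0):
            raise ConfigurationError("learning_slope must lie in (0, 1]")
        if not (0.0 < self.technology_start <= self.technology_max <= 1.0):
            raise ConfigurationError("technology_start/technology_max out of range")
        if not (0.0 <= self.accident_prob <= 1.0):
            raise ConfigurationError("accident_prob must lie in [0, 1]")
        if self.grid_side < 1:
            raise ConfigurationError("grid_side must be >= 1")
        for name in ("radiation", "impact", "regolith", "quake", "durables", "unexpected"):
            lo, hi = getattr(self, name).support()
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"{name} probability support must lie in [0, 1]")
        for freq_name in ("shipment_frequency", "base_replacement_frequency",
                          "gateway_replacement_frequency", "transfer_frequency"):
            if getattr(self, freq_name) < 0:
                raise ConfigurationError(f"{freq_name} must be >= 0")
        if abs(self.psych.w_coping + self.psych.w_tension - 1.0) > 1e-12:
            raise ConfigurationError("psych penalty weights must sum to 1")
        w = self.tlx
        if min(w.w_tension, w.w_coping, w.w_tasks) < 0 or \
                abs(w.w_tension + w.w_coping + w.w_tasks - 1.0) > 1e-12:
            raise ConfigurationError("tlx weights must be nonnegative and sum to 1")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("radiation", "impact", "regolith", "quake", "durables", "unexpected"):
            d[name] = getattr(self, name).to_spec()
        return d

    @staticmethod
    def from_dict(d: dict) -> "ScenarioConfig":
        d = dict(d)
        for name in ("radiation", "impact", "regolith", "quake", "durables", "unexpected"):
            if name in d:
                d[name] = Dist.from_spec(d[name])
        if isinstance(d.get("psych"), dict):
            d["psych"] = PsychParams(**d["psych"])
        if isinstance(d.get("tlx"), dict):
            d["tlx"] = TLXConfig(**d["tlx"])
        cfg = ScenarioConfig(**d)
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "ScenarioConfig":
        return ScenarioConfig.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Scenario presets

PRESET_NAMES = ("initial", "case1", "case2", "case3", "case4", "case5",
                "case6", "case7", "case8", "case9")


def make_scenario(preset_name: str, overrides: Optional[dict] = None) -> ScenarioConfig:
    """Return a named scenario preset with optional field overrides.

    ``initial`` is the baseline: 4 astronauts, 2 rovers, 3-month mission,
    learning slope 0.85.  The nine cases vary crew size, crew transfer and
    replacement cadence, unexpected-task probability, learning slope,
    duration, a scripted crew death, and best/worst workload parameter
    bundles.
    """
    if preset_name not in PRESET_NAMES:
        raise ConfigurationError(f"unknown preset {preset_name!r}; choose from {PRESET_NAMES}")
    cfg = ScenarioConfig(name=preset_name)
    if preset_name == "case1":
        cfg.n_astronauts = 10
    elif preset_name == "case2":
        cfg.transfer_frequency = 336
    elif preset_name == "case3":
        cfg.unexpected = fixed(0.90)
    elif preset_name == "case4":
        cfg.learning_slope = 0.95
    elif preset_name == "case5":
        cfg.duration_hours = 4032
    elif preset_name == "case6":
        cfg.scripted_death_hour = (2 * cfg.duration_hours) // 3
    elif preset_name == "case7":
        cfg.base_replacement_frequency = 0
        cfg.gateway_replacement_frequency = 0
    elif preset_name == "case8":
        # Best case (minimum workload): larger crew, 2-week resupply,
        # minimal adverse environmental probabilities, shallow 0.75 slope.
        cfg.n_astronauts = 6
        cfg.shipment_frequency = 336
        cfg.learning_slope = 0.75
        cfg.radiation = fixed(0.005)
        cfg.regolith = fixed(0.05)
        cfg.durables = fixed(0.0001)
        cfg.unexpected = fixed(0.0)
    elif preset_name == "case9":
        # Worst case (maximum workload): monthly resupply, moderate/high
        # adverse probabilities, steep 0.95 slope.
        cfg.shipment_frequency = 720
        cfg.learning_slope = 0.95
        cfg.radiation = fixed(0.024)
        cfg.regolith = fixed(0.17)
        cfg.durables = fixed(0.0008)
        cfg.unexpected = fixed(0.90)
    if overrides:
        for key, value in overrides.items():
            if not hasattr(cfg, key):
                raise ConfigurationError(f"unknown configuration field {key!r}")
            if key in ("radiation", "impact", "regolith", "quake", "durables", "unexpected"):
                value = Dist.from_spec(value)
            setattr(cfg, key, value)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# World


@dataclass
class WorldState:
    """The complete mutable simulation state."""

    config: ScenarioConfig
    rng: np.random.Generator
    crew: list
    rovers: list
    base: HabitatState
    gateway: HabitatState
    shuttle: ShuttleState
    lander: LanderState
    hour: int = 0
    next_agent_id: int = 0
    explored: set = field(default_factory=set)
    deaths: int = 0

    def habitat(self, kind: str) -> HabitatState:
        return self.base if kind == MOON_BASE else self.gateway

    def crew_of(self, kind: str) -> list:
        return [a for a in self.crew if a.alive and a.habitat_assignment == kind]

    @property
    def alive_crew(self) -> list:
        return [a for a in self.crew if a.alive]

    @property
    def base_position(self) -> tuple:
        return self.base.position


SeedLike = Union[int, Sequence[int]]


def _new_astronaut(world_or_rng, config: ScenarioConfig, agent_id: int,
                   habitat: str, rng: np.random.Generator,
                   base_position: Optional[tuple]) -> AstronautState:
    skills = {s: float(rng.random()) for s in ASTRONAUT_SKILLS}
    personality = PERSONALITIES[int(rng.integers(0, 4))]
    return AstronautState(
        id=agent_id,
        skills=skills,
        personality_type=personality,
        habitat_assignment=habitat,
        position=base_position if habitat == MOON_BASE else None,
        technology_level=config.technology_start,
        learning_rate=config.learning_slope,
    )


def fresh_astronaut(world: "WorldState", habitat: str) -> AstronautState:
    """Create a replacement crew member (fresh psychology, random skills)."""
    a = _new_astronaut(world, world.config, world.next_agent_id, habitat,
                       world.rng, world.base.position)
    world.next_agent_id += 1
    return a


def initialize_world(config: ScenarioConfig, seed: SeedLike) -> WorldState:
    """Construct the initial world for ``config``, deterministic in ``seed``.

    The crew is split evenly between Moon Base and Gateway (odd counts give
    the extra member to the surface base); skills are drawn uniformly on
    [0, 1]; personalities uniformly over the four DISC types; habitat stocks
    start at 180-day supply levels; exogenous event probabilities are
    realized once per run from their configured distributions.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_astronauts
    center = (config.grid_side // 2, config.grid_side // 2)

    def stocks(crew_count: int) -> dict:
        return {
            "air": INITIAL_SUPPLY_DAYS * crew_count * DAILY_AIR_KG,
            "water": INITIAL_SUPPLY_DAYS * crew_count * DAILY_WATER_KG,
            "food": INITIAL_SUPPLY_DAYS * crew_count * DAILY_FOOD_KG,
        }

    n_base = n - n // 2  # odd crews: extra member on the surface
    n_gateway = n // 2

    base = HabitatState(kind=MOON_BASE, energy=6000.0, position=center,
                        **stocks(n_base))
    gateway = HabitatState(kind=GATEWAY, energy=4500.0, **stocks(n_gateway))
    for hab, cfg_draw in ((base, True), (gateway, False)):
        hab.event_rates = EventRates(
            radiation_daily=config.radiation.draw(rng),
            impact_daily=config.impact.draw(rng) if cfg_draw else 0.0,
            regolith_daily=config.regolith.draw(rng) if cfg_draw else 0.0,
            quake_daily=config.quake.draw(rng) if cfg_draw else 0.0,
            durables_daily=config.durables.draw(rng),
            unexpected_daily=config.unexpected.draw(rng),
        )
        hab.init_ledger()

    world = WorldState(
        config=config, rng=rng, crew=[], rovers=[],
        base=base, gateway=gateway,
        shuttle=ShuttleState(
            shipment_frequency=config.shipment_frequency,
            base_replacement_frequency=config.base_replacement_frequency,
            gateway_replacement_frequency=config.gateway_replacement_frequency,
            accident_prob=config.accident_prob,
        ),
        lander=LanderState(transfer_frequency=config.transfer_frequency),
    )
    for i in range(n):
        habitat = MOON_BASE if i < n_base else GATEWAY
        world.crew.append(_new_astronaut(world, config, i, habitat, rng, center))
    world.next_agent_id = n
    for j in range(config.n_rovers):
        world.rovers.append(RoverState(
            id=world.next_agent_id,
            skills={s: float(rng.random()) for s in ROVER_SKILLS},
            position=center,
        ))
        world.next_agent_id += 1
    world.explored.add(center)
    return world
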