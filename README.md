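# lunarbase

An agent-based simulator of astronaut crews operating a lunar surface base
and an orbiting Gateway station, built for mission planners and human-factors
researchers who want to study how team psychology, skill mix, and
environmental shocks shape the productivity and workload of long-duration
crewed missions.

## The model

The simulation steps one Earth hour at a time through a fixed daily crew
schedule (mission planning, base operations, EVA surface blocks, resource
production, sleep). Each astronaut carries professional skill ratings
`S ∈ [0,1]` for EVA, science, engineering, and flight operations, a DISC
personality type, and two psychological scalars: **coping capacity**
(personal well-being, starts at 1.0) and **tension** (interpersonal strain,
starts at 0.0). Whether a task slot succeeds is decided by the disposition
rule

```
D(t) = [ S_i (1 − E_i(t)) + S_j (1 − E_j(t)) ] · T(t),    success ⇔ D ≥ τ
```

where `E = ½(1 − coping) + ½·tension` is the emotional penalty, the `j`
term appears only when a partner assists, `τ` is the task's (random)
cumulative skill requirement, and `T(t)` is an experience factor from the
inverse Wright learning curve `Y = A X^b`, `b = log(slope)/log 2`: each
doubling of an astronaut's completed repetitive tasks (assembly,
maintenance, mission planning) divides the factor by the slope (default
85%, the aerospace benchmark), capped at 1. Rovers run the same rule with
no affect and no learning.

Psychology evolves through DISC pair compatibility (clashing pairs such as
dominant–steady lose 0.05 coping and gain 0.05 tension per joint task;
complementary pairs get the mirror bonus), stressors from exogenous events
(−0.05 coping each), small tension increments on task failures, and nightly
recovery. Exogenous daily hazards are derived from observational rates via
Poisson arguments — micrometeoroid impact gardening (p ≈ 0.80/day), solar
particle events (0.005–0.024/day), EVA-suit regolith wear (0.05–0.17/day),
moonquakes, and equipment failures — and each event stresses the crew and
spawns unexpected troubleshooting work. Shuttles deliver a 30-day resupply
per crew member every 60 days (accident probability 2/31 per flight) and
rotate crews; running out of air, water, or food kills the crew.

A Monte Carlo driver aggregates mission outputs — tasks completed, mean
coping, mean tension — and a **synthetic TLX** workload score on 0–100,
affinely calibrated so the baseline ensemble matches the EDEN ISS analog
study (mean 60.0, SD 12.1). Ten scenario presets (`initial`, `case1` …
`case9`) vary crew size, transfer and replacement cadence, unexpected-task
load, learning slope, mission duration, and crew loss.

## Worked example

```bash
lunarbase run --scenario initial --iterations 200 --seed 7 --out demo/
```

prints

```
tasks_completed: mean=786.075 sd=259.366 median=797.500 p85=1054.150
coping_mean: mean=0.649 sd=0.231 median=0.642 p85=0.927
tension_mean: mean=0.547 sd=0.204 median=0.560 p85=0.757
raw_tlx: mean=55.846 sd=15.910 median=56.858 p85=73.248
calibrated_tlx: mean=60.440 sd=13.067 median=61.271 p85=74.733
```

Read this as: over 200 simulated 3-month missions of 4 astronauts and 2
rovers, the crew completed on average ~786 of its scheduled task slots
(roughly a fifth of the nominal quarter's 3,780-slot workload); mean coping
capacity stayed near 0.65 while interpersonal tension averaged ~0.55; and
the calibrated synthetic TLX centers on the EDEN ISS scale at ~60 points,
with 85% of missions below ~75 — a moderate-to-high but acceptable
workload. `demo/` receives `runs.csv` (one row per mission) and
`summary.json`.

Other entry points:

```bash
lunarbase scenarios                      # list the presets
lunarbase compare initial case1 case5 -n 500 --seed 7 --out cmp/
lunarbase calibrate-ref --seed 20250     # recompute the TLX reference moments
```

or from Python:

```python
from lunarbase import make_scenario, run_mission, run_monte_carlo

record = run_mission(make_scenario("case5"), seed=1)
records, summary = run_monte_carlo(make_scenario("initial"), 1000, base_seed=42)
```

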