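"""Monte Carlo driver, summary statistics, empirical CDFs, scenario tables.

Each iteration runs one full mission with an independent RNG stream keyed
by ``(base_seed, iteration)``, so the ensemble is reproducible and
embarrassingly parallel in contract.  Summaries report mean, SD, min, max,
median, and the 15th/50th/85th percentiles (linear interpolation) for each
output variable; scenario tables show each case's mean with its percent
change from the baseline scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from lunarbase.domain import ScenarioConfig
from lunarbase.scheduler import RunRecord, run_mission

__all__ = [
    "MCSummary",
    "run_monte_carlo",
    "summarize",
    "scenario_table",
    "empirical_cdf",
    "EmpiricalCDF",
    "OUTPUT_VARS",
]

OUTPUT_VARS = ("tasks_completed", "coping_mean", "tension_mean",
               "raw_tlx", "calibrated_tlx")


def summarize(values: Sequence[float]) -> dict:
    """{mean, sd, min, max, median, p15, p50, p85} of a sample (sd=0 for n=1)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    p15, p50, p85 = np.percentile(x, [15, 50, 85])
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "min": float(x.min()),
        "max": float(x.max()),
        "median": float(np.median(x)),
        "p15": float(p15),
        "p50": float(p50),
        "p85": float(p85),
    }


@dataclass
class MCSummary:
    """Cross-iteration summary of one scenario's Monte Carlo ensemble."""

    scenario: str
    n_iterations: int
    stats: Dict[str, dict]
    values: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def run_monte_carlo(config: ScenarioConfig, n_iter: int, base_seed: int,
                    keep_records: bool = False):
    """Run ``n_iter`` independent missions of ``config``.

    Returns ``(records, summary)``; ``records`` is the per-iteration
    :class:`RunRecord` list when ``keep_records`` is set, else empty (the
    raw output arrays are always available in ``summary.values``).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    records: List[RunRecord] = []
    values = {var: np.empty(n_iter) for var in OUTPUT_VARS}
    for i in range(n_iter):
        rec = run_mission(config, seed=[base_seed, i])
        for var in OUTPUT_VARS:
            values[var][i] = getattr(rec, var)
        if keep_records:
            records.append(rec)
    stats = {var: summarize(vals) for var, vals in values.items()}
    return records, MCSummary(scenario=config.name, n_iterations=n_iter,
                              stats=stats, values=values)


def scenario_table(summaries: List[MCSummary],
                   baseline: str = "initial") -> Dict[str, pd.DataFrame]:
    """One comparison table per output variable.

    Rows are scenarios; columns are mean, percent change of the mean versus
    the baseline scenario, SD, min, max, and median.
    """
    names = [s.scenario for s in summaries]
    if baseline not in names:
        raise ValueError(f"baseline scenario {baseline!r} missing from summaries")
    base = next(s for s in summaries if s.scenario == baseline)
    tables: Dict[str, pd.DataFrame] = {}
    for var in OUTPUT_VARS:
        rows = []
        base_mean = base.stats[var]["mean"]
        for s in summaries:
            st = s.stats[var]
            pct = (100.0 * (st["mean"] - base_mean) / base_mean
                   if base_mean != 0 else float("nan"))
            rows.append({
                "scenario": s.scenario, "mean": st["mean"],
                "pct_change": pct, "sd": st["sd"], "min": st["min"],
                "max": st["max"], "median": st["median"],
            })
        tables[var] = pd.DataFrame(rows).set_index("scenario")
    return tables


class EmpiricalCDF:
    """Right-continuous empirical CDF with linear-interpolation percentiles."""

    def __init__(self, values: Sequence[float]):
        x = np.asarray(values, dtype=float)
        if x.size == 0:
            raise ValueError("empirical CDF requires a nonempty sample")
        self._sorted = np.sort(x)

    def __call__(self, x: float) -> float:
        return float(np.searchsorted(self._sorted, x, side="right")) / self._sorted.size

    def percentile(self, p: float) -> float:
        """p-th percentile (0-100), linear interpolation between order stats."""
        return float(np.percentile(self._sorted, p))


def empirical_cdf(values: Sequence[float]) -> EmpiricalCDF:
    return EmpiricalCDF(values)
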