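"""Replicated density sweeps and their aggregation.

A sweep runs many independent simulations over a grid of reputation-seeker
densities (and optionally several lattice sizes), producing one tidy
record per run and per-(size, density) summaries: mean silence, mean cycle
length, mean and minimum theta, scenario frequencies and mean local-state
fractions.  Every run's seed is derived from the master seed by a
counter-free scheme keyed on (size, density, replicate), so any single row
can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .dynamics import run_simulation
from .lattice import LOCAL_STATE_NAMES, SimulationConfig
from .observables import SCENARIO_LABELS, equilibrium_record

DEFAULT_DENSITY_GRID: tuple[float, ...] = tuple(
    round(0.05 * k, 2) for k in range(21)
)

_FRACTION_COLUMNS = [f"frac_{name}" for name in LOCAL_STATE_NAMES]

RECORD_COLUMNS = [
    "size", "density", "replicate", "seed",
    "delta_A", "cycle_length", "transient_length", "censored",
    "silence_density", "delta_E_mean", "theta", "scenario",
    *_FRACTION_COLUMNS,
]


@dataclasses.dataclass(frozen=True)
class SweepPlan:
    """Specification of a replicated density sweep.

    ``sizes`` are agent counts and must be perfect squares (the lattice
    side is their square root).  ``max_steps`` here is the desk-scale
    default of 2000 synchronous updates; equilibria are almost always
    reached much earlier.
    """

    densities: tuple[float, ...] = DEFAULT_DENSITY_GRID
    replicates: int = 200
    sizes: tuple[int, ...] = (100,)
    base_seed: int = 0
    max_steps: int = 2000
    p_attitude_a: float = 0.5
    p_initial_express: float = 0.5
    epsilon_correspondence: float = 0.05

    def __post_init__(self) -> None:
        if len(self.densities) == 0 or any(not 0 <= d <= 1 for d in self.densities):
            raise ValueError("densities: must be nonempty with values in [0, 1]")
        if any(b <= a for a, b in zip(self.densities, self.densities[1:])):
            raise ValueError("densities: must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates: must be >= 1")
        for size in self.sizes:
            side = int(round(size ** 0.5))
            if side * side != size or side < 2:
                raise ValueError(f"sizes: {size} is not a perfect square >= 4")
        if self.max_steps < 1:
            raise ValueError("max_steps: must be >= 1")

    @property
    def n_runs(self) -> int:
        return len(self.sizes) * len(self.densities) * self.replicates


def derive_run_seed(base_seed: int, size: int, density: float, replicate: int) -> int:
    """Deterministic per-run seed keyed on the run's identity.

    Independent of enumeration order, so a single (size, density,
    replicate) row can be replayed without re-running the sweep.  Kept
    below 2**31.
    """
    key = (int(base_seed), int(size), int(round(density * 10000)), int(replicate))
    seq = np.random.SeedSequence(key)
    return int(seq.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def run_single(plan: SweepPlan, size: int, density: float, replicate: int) -> dict:
    """Execute one sweep cell and return its tidy record row."""
    seed = derive_run_seed(plan.base_seed, size, density, replicate)
    config = SimulationConfig(
        lattice_side=int(round(size ** 0.5)),
        r_density=density,
        p_attitude_a=plan.p_attitude_a,
        p_initial_express=plan.p_initial_express,
        max_steps=plan.max_steps,
        seed=seed,
        epsilon_correspondence=plan.epsilon_correspondence,
    )
    trajectory, cycle = run_simulation(config)
    record = equilibrium_record(trajectory, cycle, epsilon=plan.epsilon_correspondence)
    row = {"size": size, "density": density, "replicate": replicate, "seed": seed}
    row.update(record.as_dict())
    return row


def run_sweep(
    plan: SweepPlan,
    on_record: Callable[[dict], None] | None = None,
    skip: Iterable[tuple[int, float, int]] = (),
    progress: Callable[[int, float], None] | None = None,
) -> pd.DataFrame:
    """Run every (size, density, replicate) cell of the plan.

    ``on_record`` is invoked with each finished row (used for incremental
    flushing); ``skip`` lists already-completed (size, density, replicate)
    keys so an interrupted sweep can resume; ``progress`` is called once
    per (size, density) group.
    """
    skip_set = {(int(s), round(float(d), 6), int(r)) for s, d, r in skip}
    rows: list[dict] = []
    for size in plan.sizes:
        for density in plan.densities:
            if progress is not None:
                progress(size, density)
            for replicate in range(plan.replicates):
                if (size, round(float(density), 6), replicate) in skip_set:
                    continue
                row = run_single(plan, size, density, replicate)
                rows.append(row)
                if on_record is not None:
                    on_record(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def summarize_by_density(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-run records into one row per (size, density).

    Scenario frequencies are computed over runs with a defined theta
    (nonzero attitude gap); excluded and censored runs are counted, never
    silently dropped.
    """
    if len(records) == 0:
        raise ValueError("records: must be nonempty")
    summaries = []
    for (size, density), group in records.groupby(["size", "density"], sort=True):
        defined = group[group["delta_A"] != 0]
        row = {
            "size": size,
            "density": density,
            "n_runs": len(group),
            "n_theta_undefined": int((group["delta_A"] == 0).sum()),
            "n_censored": int(group["censored"].sum()),
            "silence_mean": group["silence_density"].mean(),
            "silence_std": group["silence_density"].std(ddof=0),
            "cycle_length_mean": group["cycle_length"].mean(),
            "cycle_length_std": group["cycle_length"].std(ddof=0),
            "theta_mean": defined["theta"].mean() if len(defined) else np.nan,
            "theta_min": defined["theta"].min() if len(defined) else np.nan,
        }
        for label in SCENARIO_LABELS:
            row[f"p_{label}"] = (
                (defined["scenario"] == label).mean() if len(defined) else np.nan
            )
        for column in _FRACTION_COLUMNS:
            row[column] = group[column].mean()
        summaries.append(row)
    return pd.DataFrame(summaries)


def locate_extremum(
    summary: pd.DataFrame,
    field: str,
    mode: str = "max",
    size: int | None = None,
) -> float:
    """Grid density at which a per-density mean is extremal.

    Ties are broken toward the lower density.  ``size`` selects a lattice
    size when the summary covers several; with a single size it may be
    omitted.
    """
    if field not in summary.columns:
        raise ValueError(f"field: unknown column {field!r}")
    if mode not in ("max", "min"):
        raise ValueError("mode: must be 'max' or 'min'")
    table = summary
    if size is not None:
        table = summary[summary["size"] == size]
    elif summary["size"].nunique() > 1:
        raise ValueError("size: required when the summary covers several sizes")
    if table["density"].nunique() < 2:
        raise ValueError("summary: need at least 2 densities")
    table = table.sort_values("density")
    values = table[field].to_numpy()
    idx = int(np.nanargmax(values) if mode == "max" else np.nanargmin(values))
    return float(table["density"].iloc[idx])


@dataclasses.dataclass(frozen=True)
class ScenarioProfile:
    """Per-density modal scenarios and the two contiguous regimes.

    ``modal`` maps each density to the most frequent defined-theta
    scenario ("tie" when two labels are equally frequent).
    ``amplified_prefix_end`` is the largest density such that amplified
    majority is modal at *every* grid density from the start up to and
    including it (``None`` if it is not modal at the first density);
    ``dampened_suffix_start`` is the smallest density from which dampened
    majority is modal through the end of the grid (``None`` likewise).
    """

    modal: dict[float, str]
    amplified_prefix_end: float | None
    dampened_suffix_start: float | None


def modal_scenario_profile(summary: pd.DataFrame, size: int | None = None) -> ScenarioProfile:
    """Most frequent scenario per density, plus the regime boundaries."""
    table = summary
    if size is not None:
        table = summary[summary["size"] == size]
    elif summary["size"].nunique() > 1:
        raise ValueError("size: required when the summary covers several sizes")
    table = table.sort_values("density")

    modal: dict[float, str] = {}
    for _, row in table.iterrows():
        freqs = {label: row[f"p_{label}"] for label in SCENARIO_LABELS}
        if all(pd.isna(v) for v in freqs.values()):
            modal[row["density"]] = "undefined"
            continue
        best = max(freqs.values())
        winners = [label for label, v in freqs.items() if v == best]
        modal[row["density"]] = winners[0] if len(winners) == 1 else "tie"

    densities = list(modal)
    amplified_end = None
    for d in densities:
        if modal[d] != "amplified_majority":
            break
        amplified_end = d
    dampened_start = None
    for d in reversed(densities):
        if modal[d] != "dampened_majority":
            break
        dampened_start = d
    return ScenarioProfile(modal=modal,
                           amplified_prefix_end=amplified_end,
                           dampened_suffix_start=dampened_start)


__all__ = [
    "DEFAULT_DENSITY_GRID",
    "RECORD_COLUMNS",
    "SweepPlan",
    "ScenarioProfile",
    "derive_run_seed",
    "run_single",
    "run_sweep",
    "summarize_by_density",
    "locate_extremum",
    "modal_scenario_profile",
]
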