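"""Equilibrium observables and scenario classification.

The macroscopic description of a run compares what the population *thinks*
with what it *says*:

* attitude gap ``delta_A`` — (# agents privately holding ``a``) minus
  (# holding ``b``); fixed for the whole run;
* expressed gap ``delta_E(t)`` — (# agents voicing ``a``) minus
  (# voicing ``b``) at step ``t``;
* public-private opinion discrepancy ``theta`` — the mean of ``delta_E``
  over the equilibrium window divided by ``delta_A``.

``theta`` sorts equilibria into four scenarios: *amplified majority*
(``theta > 1``: the voiced majority overstates the attitudinal one),
*correspondence* (``theta`` within a tolerance band of 1), *dampened
majority* (``0 <= theta < 1``), and *silent majority* (``theta < 0``: the
voiced majority is the attitudinal minority).  Runs with ``delta_A = 0``
have no majority to compare against; ``theta`` is undefined and such runs
are flagged and excluded from scenario aggregates.

The equilibrium window is the final ``cycle_length`` steps of the
trajectory when a cycle was found (exactly one full period); for censored
runs the final 10% of recorded steps are used and the record keeps the
censored flag.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .dynamics import CycleInfo, Trajectory
from .lattice import (
    ATTITUDE_A,
    ATTITUDE_B,
    EXPRESS,
    LOCAL_STATE_NAMES,
    LatticeState,
    classify_local_states_grid,
    expressed_opinion_grids,
    neighbor_expressed_counts,
)

SCENARIO_AMPLIFIED = "amplified_majority"
SCENARIO_CORRESPONDENCE = "correspondence"
SCENARIO_DAMPENED = "dampened_majority"
SCENARIO_SILENT_MAJORITY = "silent_majority"
SCENARIO_UNDEFINED = "undefined"

SCENARIO_LABELS: tuple[str, ...] = (
    SCENARIO_AMPLIFIED,
    SCENARIO_CORRESPONDENCE,
    SCENARIO_DAMPENED,
    SCENARIO_SILENT_MAJORITY,
)

#: Fraction of the trajectory used as the equilibrium window when no cycle
#: was detected within the horizon.
CENSORED_WINDOW_FRACTION = 0.10


def count_silent(state: LatticeState) -> int:
    """Number of agents not expressing at this step."""
    return int(state.n_agents - np.count_nonzero(state.behavior_grid == EXPRESS))


def expressed_gap(state: LatticeState) -> int:
    """delta_E: voiced-``a`` count minus voiced-``b`` count at this step."""
    voices_a, voices_b = expressed_opinion_grids(state)
    return int(voices_a.sum()) - int(voices_b.sum())


def attitude_gap(state: LatticeState) -> int:
    """delta_A: ``a``-attitude count minus ``b``-attitude count (constant)."""
    return int(np.count_nonzero(state.attitude_grid == ATTITUDE_A)
               - np.count_nonzero(state.attitude_grid == ATTITUDE_B))


def silence_density(states: Sequence[LatticeState]) -> float:
    """Mean fraction of silent agents over a window of states."""
    if len(states) == 0:
        raise ValueError("states: window must be nonempty")
    return float(np.mean([count_silent(s) / s.n_agents for s in states]))


def local_state_distribution(states: Sequence[LatticeState]) -> np.ndarray:
    """Window-averaged fractions of the five local network states.

    Every agent is classified by its own four neighbours' voiced opinions
    at every step of the window; the five fractions sum to 1.
    """
    if len(states) == 0:
        raise ValueError("states: window must be nonempty")
    totals = np.zeros(len(LOCAL_STATE_NAMES), dtype=np.int64)
    for state in states:
        n_a, n_b = neighbor_expressed_counts(state)
        labels = classify_local_states_grid(n_a, n_b)
        totals += np.bincount(labels.ravel(), minlength=len(LOCAL_STATE_NAMES))
    return totals / totals.sum()


def discrepancy_theta(delta_e_window_mean: float, delta_a: int) -> float:
    """theta = windowed mean expressed gap / attitude gap.

    Returns ``nan`` when ``delta_a`` is zero: with perfectly tied
    attitudes there is no majority whose representation could be measured.
    """
    if delta_a == 0:
        return math.nan
    return delta_e_window_mean / delta_a


def classify_scenario(theta: float, epsilon: float = 0.05) -> str:
    """Map a finite theta to one of the four equilibrium scenarios.

    ``theta < 0`` is a silent majority (sign inversion); values in
    ``[1 - epsilon, 1 + epsilon]`` count as correspondence; below that
    band the majority is dampened (``theta = 0`` included), above it
    amplified.  ``nan`` maps to the undefined label.
    """
    if epsilon < 0:
        raise ValueError("epsilon: must be nonnegative")
    if math.isnan(theta):
        return SCENARIO_UNDEFINED
    if theta < 0:
        return SCENARIO_SILENT_MAJORITY
    if theta < 1 - epsilon:
        return SCENARIO_DAMPENED
    if theta <= 1 + epsilon:
        return SCENARIO_CORRESPONDENCE
    return SCENARIO_AMPLIFIED


@dataclasses.dataclass(frozen=True)
class EquilibriumRecord:
    """One run's equilibrium summary (one tidy CSV row)."""

    delta_A: int
    delta_E_mean: float
    theta: float
    silence_density: float
    local_state_fractions: tuple[float, float, float, float, float]
    scenario: str
    cycle_length: int
    transient_length: int
    censored: bool

    def as_dict(self) -> dict:
        row = dataclasses.asdict(self)
        fractions = row.pop("local_state_fractions")
        for name, value in zip(LOCAL_STATE_NAMES, fractions):
            row[f"frac_{name}"] = value
        return row


def equilibrium_window(trajectory: Trajectory, cycle: CycleInfo) -> slice:
    """Index slice of the equilibrium window within the trajectory."""
    n = len(trajectory)
    if cycle.censored:
        width = max(1, int(round(CENSORED_WINDOW_FRACTION * n)))
    else:
        width = min(cycle.cycle_length, n)
    return slice(n - width, n)


def equilibrium_record(
    trajectory: Trajectory,
    cycle: CycleInfo,
    epsilon: float = 0.05,
) -> EquilibriumRecord:
    """Summarize a finished run over its equilibrium window."""
    window = equilibrium_window(trajectory, cycle)
    n = trajectory.n_agents

    delta_a = int(np.count_nonzero(trajectory.attitude_grid == ATTITUDE_A)
                  - np.count_nonzero(trajectory.attitude_grid == ATTITUDE_B))
    delta_e_mean = float(trajectory.delta_e[window].mean())
    theta = discrepancy_theta(delta_e_mean, delta_a)
    window_counts = trajectory.local_state_counts[window].sum(axis=0)

    return EquilibriumRecord(
        delta_A=delta_a,
        delta_E_mean=delta_e_mean,
        theta=theta,
        silence_density=float(trajectory.silent_counts[window].mean()) / n,
        local_state_fractions=tuple(window_counts / window_counts.sum()),
        scenario=classify_scenario(theta, epsilon),
        cycle_length=cycle.cycle_length,
        transient_length=cycle.transient_length,
        censored=cycle.censored,
    )


__all__ = [
    "SCENARIO_AMPLIFIED",
    "SCENARIO_CORRESPONDENCE",
    "SCENARIO_DAMPENED",
    "SCENARIO_SILENT_MAJORITY",
    "SCENARIO_UNDEFINED",
    "SCENARIO_LABELS",
    "EquilibriumRecord",
    "count_silent",
    "expressed_gap",
    "attitude_gap",
    "silence_density",
    "local_state_distribution",
    "discrepancy_theta",
    "classify_scenario",
    "equilibrium_window",
    "equilibrium_record",
]
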