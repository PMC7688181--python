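"""Synchronous time evolution and exact equilibrium detection.

All agents update simultaneously: the behavior of every agent at ``t + 1``
is a deterministic function of the *whole* behavior grid at ``t`` (types
and attitudes are frozen).  The state space is finite (``2**N`` behavior
configurations), so every run eventually revisits a configuration, after
which the dynamics repeat forever.  The first revisited configuration
therefore marks the start of the run's limit cycle; a cycle of length 1 is
a fixed point (a frozen public-opinion pattern).

Two cycle-length measures are provided:

* :func:`detect_cycle_exact` — first recurrence of the full behavior
  configuration.  Exact for deterministic dynamics and the primary
  detector.
* :func:`estimate_cycle_paper` — the max-of-min-recurrence-lags statistic
  over the second half of a fixed-horizon trajectory.  It equals the exact
  period whenever the transient ends before half-horizon and the cycle
  fits in the remaining window; it is kept for cross-validation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .lattice import (
    LatticeState,
    SimulationConfig,
    classify_local_states_grid,
    decide_behavior_grid,
    expressed_opinion_grids,
    init_lattice,
    neighbor_expressed_counts,
)

#: Sentinel returned by :func:`estimate_cycle_paper` when some point in the
#: evaluation window never recurs within the trajectory.
CENSORED: int = -1

_N_LOCAL_STATES = 5


@dataclasses.dataclass(frozen=True)
class CycleInfo:
    """Equilibrium summary of one run.

    ``transient_length`` counts the steps before the first entry into the
    cycle; ``cycle_length`` is the period (1 = fixed point).  ``censored``
    is set when no configuration recurred within the horizon, in which
    case ``cycle_length`` is capped at the number of recorded steps.
    """

    transient_length: int
    cycle_length: int
    censored: bool = False


@dataclasses.dataclass
class Trajectory:
    """Per-step record of one run.

    Stores the packed behavior configuration plus the cheap per-step
    observables (silent count, expressed-opinion gap, counts of the five
    local network states), together with the frozen type and attitude
    grids so that any step's full :class:`LatticeState` can be rebuilt.
    """

    type_grid: np.ndarray
    attitude_grid: np.ndarray
    configs: list[bytes]
    silent_counts: np.ndarray
    delta_e: np.ndarray
    local_state_counts: np.ndarray  # shape (T, 5)

    def __len__(self) -> int:
        return len(self.configs)

    @property
    def n_agents(self) -> int:
        return self.type_grid.size

    def state_at(self, t: int) -> LatticeState:
        """Rebuild the full lattice state at step ``t``."""
        side = self.type_grid.shape[0]
        behavior = np.unpackbits(
            np.frombuffer(self.configs[t], dtype=np.uint8), count=self.n_agents
        ).reshape(side, side)
        return LatticeState(self.type_grid, self.attitude_grid, behavior, t=t)


def synchronous_step(state: LatticeState) -> LatticeState:
    """Apply one parallel update to every agent; types/attitudes unchanged."""
    n_a, n_b = neighbor_expressed_counts(state)
    behavior = decide_behavior_grid(state.type_grid, state.attitude_grid, n_a, n_b)
    return state.with_behavior(behavior, state.t + 1)


def run_from_state(
    state: LatticeState,
    max_steps: int,
    stop_on_recurrence: bool = True,
) -> tuple[Trajectory, CycleInfo]:
    """Evolve an initial state, recording up to ``max_steps`` configurations.

    With ``stop_on_recurrence`` the loop halts as soon as the current
    configuration has been seen before — the exact cycle is then known and
    the trajectory's final ``cycle_length`` entries cover it exactly once.
    With ``stop_on_recurrence=False`` the full horizon is recorded (needed
    by the fixed-horizon cycle estimator); the recurrence bookkeeping is
    identical.
    """
    type_grid = state.type_grid
    attitude_grid = state.attitude_grid
    behavior = state.behavior_grid.astype(bool)
    attitude_is_a = attitude_grid == 0
    is_reputation = type_grid == 1

    configs: list[bytes] = []
    silent_counts = np.empty(max_steps, dtype=np.int32)
    delta_e = np.empty(max_steps, dtype=np.int32)
    local_counts = np.empty((max_steps, _N_LOCAL_STATES), dtype=np.int32)

    seen: dict[bytes, int] = {}
    cycle: CycleInfo | None = None

    for t in range(max_steps):
        voices_a = behavior & attitude_is_a
        voices_b = behavior & ~attitude_is_a
        n_a = _neighbor_sum(voices_a)
        n_b = _neighbor_sum(voices_b)

        key = np.packbits(behavior).tobytes()
        configs.append(key)
        expressed_a = int(voices_a.sum())
        expressed_b = int(voices_b.sum())
        silent_counts[t] = behavior.size - expressed_a - expressed_b
        delta_e[t] = expressed_a - expressed_b
        local_counts[t] = np.bincount(
            classify_local_states_grid(n_a, n_b).ravel(), minlength=_N_LOCAL_STATES
        )

        first = seen.setdefault(key, t)
        if first != t and cycle is None:
            cycle = CycleInfo(transient_length=first, cycle_length=t - first)
            if stop_on_recurrence:
                n_recorded = t + 1
                break

        tie = n_a == n_b
        contested = (n_a > 0) & (n_b > 0) & ~tie
        att_matches_majority = attitude_is_a == (n_a > n_b)
        behavior = np.where(
            tie,
            is_reputation,
            np.where(contested,
                     is_reputation & ~att_matches_majority,
                     ~is_reputation & att_matches_majority),
        )
    else:
        n_recorded = max_steps

    if cycle is None:
        cycle = CycleInfo(transient_length=0, cycle_length=n_recorded, censored=True)

    trajectory = Trajectory(
        type_grid=type_grid,
        attitude_grid=attitude_grid,
        configs=configs,
        silent_counts=silent_counts[:n_recorded],
        delta_e=delta_e[:n_recorded],
        local_state_counts=local_counts[:n_recorded],
    )
    return trajectory, cycle


def run_simulation(
    config: SimulationConfig,
    seed: int | None = None,
    stop_on_recurrence: bool = True,
) -> tuple[Trajectory, CycleInfo]:
    """Initialize from ``config`` and evolve until recurrence or horizon."""
    state = init_lattice(config, seed=seed)
    return run_from_state(state, config.max_steps, stop_on_recurrence=stop_on_recurrence)


def detect_cycle_exact(trajectory: Trajectory) -> CycleInfo:
    """First-recurrence detection on the recorded configurations.

    Because the update is deterministic, the first repeated configuration
    identifies the cycle: if step ``t`` equals step ``t1 < t``, the
    transient has length ``t1`` and the period is ``t - t1``.
    """
    if len(trajectory) == 0:
        raise ValueError("trajectory: must be nonempty")
    seen: dict[bytes, int] = {}
    for t, key in enumerate(trajectory.configs):
        first = seen.setdefault(key, t)
        if first != t:
            return CycleInfo(transient_length=first, cycle_length=t - first)
    return CycleInfo(transient_length=0, cycle_length=len(trajectory), censored=True)


def estimate_cycle_paper(trajectory: Trajectory) -> int:
    """Cycle-length estimate from minimum recurrence lags.

    For every time point in the second half of the trajectory, find the
    smallest positive lag to an identical configuration anywhere in the
    run; the estimate is the maximum of those minima.  Returns
    :data:`CENSORED` (``-1``) when some point in the window never recurs,
    which happens when the horizon is too short for the cycle.
    """
    n = len(trajectory)
    if n < 2:
        raise ValueError("trajectory: need at least 2 steps")
    occurrences: dict[bytes, list[int]] = {}
    for t, key in enumerate(trajectory.configs):
        occurrences.setdefault(key, []).append(t)

    longest_min_lag = 0
    for t in range(n // 2, n):
        times = occurrences[trajectory.configs[t]]
        if len(times) < 2:
            return CENSORED
        i = times.index(t)
        lags = []
        if i > 0:
            lags.append(t - times[i - 1])
        if i + 1 < len(times):
            lags.append(times[i + 1] - t)
        longest_min_lag = max(longest_min_lag, min(lags))
    return longest_min_lag


def verify_trajectory(trajectory: Trajectory) -> bool:
    """Re-check that every recorded step is the synchronous image of its
    predecessor (a consistency audit used in tests and debugging)."""
    for t in range(len(trajectory) - 1):
        stepped = synchronous_step(trajectory.state_at(t))
        if not np.array_equal(stepped.behavior_grid,
                              trajectory.state_at(t + 1).behavior_grid):
            return False
    return True


def _neighbor_sum(grid: np.ndarray) -> np.ndarray:
    g = grid.astype(np.int8)
    return (np.roll(g, 1, axis=0) + np.roll(g, -1, axis=0)
            + np.roll(g, 1, axis=1) + np.roll(g, -1, axis=1))


__all__ = [
    "CENSORED",
    "CycleInfo",
    "Trajectory",
    "synchronous_step",
    "run_from_state",
    "run_simulation",
    "detect_cycle_exact",
    "estimate_cycle_paper",
    "verify_trajectory",
    "expressed_opinion_grids",
]
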