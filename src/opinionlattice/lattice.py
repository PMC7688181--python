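"""Lattice configuration and the single-agent expression rule.

The model places ``N = L**2`` agents on an ``L x L`` square lattice with
periodic boundaries, so every agent has exactly four von Neumann neighbours.
Each agent belongs to one of two fixed populations — *consensus seekers*,
who speak only to affirm an unopposed local majority, and *reputation
seekers*, who speak exactly when doing so is distinctive (silence,
stalemate, or a supported minority) — and holds a fixed binary private
attitude (``a`` or ``b``).  The only dynamic variable is the per-step
*behavior*: voice one's own attitude or stay silent.  Agents cannot lie,
so an expressing agent always voices its own attitude.

This module defines the immutable run configuration, the lattice state
container, the five-way classification of an agent's local neighbourhood,
and the deterministic per-agent decision rule.  Vectorized whole-grid
versions of the classification and decision rule live here too; the time
loop that applies them is in :mod:`opinionlattice.dynamics`.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np

# -- agent populations --------------------------------------------------------
CONSENSUS: int = 0
REPUTATION: int = 1

# -- private attitudes --------------------------------------------------------
ATTITUDE_A: int = 0
ATTITUDE_B: int = 1

# -- per-step behavior --------------------------------------------------------
SILENT: int = 0
EXPRESS: int = 1

# -- local network states (five-way partition of a neighbourhood) -------------
TOTAL_SILENCE: int = 0
STALEMATE: int = 1
MAJORITY_WITH_MINORITY: int = 2
PARTIAL_MAJORITY: int = 3
FULL_MAJORITY: int = 4

LOCAL_STATE_NAMES: tuple[str, ...] = (
    "total_silence",
    "stalemate",
    "majority_with_minority",
    "partial_majority",
    "full_majority",
)

N_NEIGHBORS: int = 4


def _require(condition: bool, field: str, message: str) -> None:
    if not condition:
        raise ValueError(f"{field}: {message}")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """All tunables of a single run.

    Parameters
    ----------
    lattice_side
        Side ``L`` of the square lattice; ``N = L**2`` agents.
    r_density
        Fraction of reputation seekers in the population, in ``[0, 1]``.
        Exactly ``round(r_density * N)`` agents are reputation seekers.
    p_attitude_a
        Probability that an agent's fixed private attitude is ``a``.
    p_initial_express
        Probability that an agent starts out expressing at ``t = 0``.
    max_steps
        Horizon: maximum number of synchronous updates per run.
    seed
        Seed for the run's random number generator.
    epsilon_correspondence
        Half-width of the symmetric tolerance band around ``theta = 1``
        inside which an equilibrium counts as *correspondence*.
    """

    lattice_side: int = 10
    r_density: float = 0.5
    p_attitude_a: float = 0.5
    p_initial_express: float = 0.5
    max_steps: int = 10000
    seed: int = 0
    epsilon_correspondence: float = 0.05

    def __post_init__(self) -> None:
        _require(int(self.lattice_side) == self.lattice_side and self.lattice_side >= 2,
                 "lattice_side", "must be an integer >= 2")
        for field in ("r_density", "p_attitude_a", "p_initial_express"):
            value = getattr(self, field)
            _require(0.0 <= value <= 1.0, field, "must lie in [0, 1]")
        _require(int(self.max_steps) == self.max_steps and self.max_steps >= 1,
                 "max_steps", "must be an integer >= 1")
        _require(self.epsilon_correspondence >= 0.0,
                 "epsilon_correspondence", "must be nonnegative")

    @property
    def n_agents(self) -> int:
        return self.lattice_side ** 2

    @property
    def n_reputation(self) -> int:
        """Exact number of reputation seekers placed on the lattice."""
        # Banker's rounding would make 0.5*N ambiguous at odd N^2/2; use
        # round-half-up so the count is monotone in r_density.
        return int(np.floor(self.r_density * self.n_agents + 0.5))


@dataclasses.dataclass
class LatticeState:
    """Full configuration of the lattice at one time step.

    ``type_grid`` and ``attitude_grid`` are frozen for the lifetime of a
    run; only ``behavior_grid`` evolves.  All grids are ``int8`` arrays of
    shape ``(L, L)``.
    """

    type_grid: np.ndarray
    attitude_grid: np.ndarray
    behavior_grid: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.type_grid = np.asarray(self.type_grid, dtype=np.int8)
        self.attitude_grid = np.asarray(self.attitude_grid, dtype=np.int8)
        self.behavior_grid = np.asarray(self.behavior_grid, dtype=np.int8)
        shape = self.type_grid.shape
        _require(self.type_grid.ndim == 2 and shape[0] == shape[1] and shape[0] >= 2,
                 "type_grid", "must be a square 2-D grid with side >= 2")
        _require(self.attitude_grid.shape == shape, "attitude_grid",
                 f"shape {self.attitude_grid.shape} != {shape}")
        _require(self.behavior_grid.shape == shape, "behavior_grid",
                 f"shape {self.behavior_grid.shape} != {shape}")
        for field, grid in (("type_grid", self.type_grid),
                            ("attitude_grid", self.attitude_grid),
                            ("behavior_grid", self.behavior_grid)):
            _require(bool(np.isin(grid, (0, 1)).all()), field, "entries must be 0 or 1")

    @property
    def side(self) -> int:
        return self.type_grid.shape[0]

    @property
    def n_agents(self) -> int:
        return self.type_grid.size

    def with_behavior(self, behavior_grid: np.ndarray, t: int) -> "LatticeState":
        """New state sharing the frozen grids with an updated behavior grid."""
        new = LatticeState.__new__(LatticeState)
        new.type_grid = self.type_grid
        new.attitude_grid = self.attitude_grid
        new.behavior_grid = np.asarray(behavior_grid, dtype=np.int8)
        new.t = t
        return new

    def copy(self) -> "LatticeState":
        return LatticeState(self.type_grid.copy(), self.attitude_grid.copy(),
                            self.behavior_grid.copy(), self.t)


class LocalCount(NamedTuple):
    """Tally of one agent's four neighbours' voiced opinions."""

    n_a: int
    n_b: int
    n_silent: int

    def validate(self) -> "LocalCount":
        if min(self) < 0 or sum(self) != N_NEIGHBORS:
            raise ValueError(
                f"LocalCount{tuple(self)}: counts must be nonnegative and sum to {N_NEIGHBORS}")
        return self


def init_lattice(config: SimulationConfig, seed: int | None = None) -> LatticeState:
    """Draw a fresh initial configuration.

    Exactly ``round(r_density * N)`` agents are reputation seekers, placed
    uniformly at random; attitudes and initial behaviors are independent
    Bernoulli draws.  The same seed always yields the same state.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_agents
    side = config.lattice_side

    types = np.full(n, CONSENSUS, dtype=np.int8)
    types[rng.permutation(n)[: config.n_reputation]] = REPUTATION
    attitudes = np.where(rng.random(n) < config.p_attitude_a, ATTITUDE_A, ATTITUDE_B)
    behaviors = np.where(rng.random(n) < config.p_initial_express, EXPRESS, SILENT)

    return LatticeState(
        type_grid=types.reshape(side, side),
        attitude_grid=attitudes.astype(np.int8).reshape(side, side),
        behavior_grid=behaviors.astype(np.int8).reshape(side, side),
        t=0,
    )


def classify_local_state(counts: LocalCount) -> int:
    """Classify a neighbour tally into one of the five local network states.

    The five classes partition the 15 admissible count triples:

    * ``TOTAL_SILENCE`` — nobody speaks;
    * ``STALEMATE`` — both opinions voiced equally often (by 1+1 or 2+2);
    * ``FULL_MAJORITY`` — all four neighbours voice the same opinion;
    * ``MAJORITY_WITH_MINORITY`` — both opinions voiced, unequally;
    * ``PARTIAL_MAJORITY`` — exactly one opinion voiced, by 1-3 neighbours.
    """
    n_a, n_b, _ = LocalCount(*counts).validate()
    if n_a + n_b == 0:
        return TOTAL_SILENCE
    if n_a == n_b:
        return STALEMATE
    if n_a == N_NEIGHBORS or n_b == N_NEIGHBORS:
        return FULL_MAJORITY
    if n_a > 0 and n_b > 0:
        return MAJORITY_WITH_MINORITY
    return PARTIAL_MAJORITY


def decide_behavior(agent_type: int, own_attitude: int, counts: LocalCount) -> int:
    """Next-step behavior of one agent given its neighbourhood tally.

    Consensus seekers affirm: they express only when their own attitude
    matches the *only* voiced opinion (partial or full majority).
    Reputation seekers innovate: they express under total silence or a
    stalemate, and as the supported minority voice when a majority faces a
    minority; they never echo the local majority.
    """
    n_a, n_b, _ = counts = LocalCount(*counts).validate()
    label = classify_local_state(counts)
    if label in (TOTAL_SILENCE, STALEMATE):
        return EXPRESS if agent_type == REPUTATION else SILENT
    majority = ATTITUDE_A if n_a > n_b else ATTITUDE_B
    if label == MAJORITY_WITH_MINORITY:
        return EXPRESS if (agent_type == REPUTATION and own_attitude != majority) else SILENT
    # PARTIAL_MAJORITY or FULL_MAJORITY: a single voiced opinion
    return EXPRESS if (agent_type == CONSENSUS and own_attitude == majority) else SILENT


# -- vectorized whole-grid helpers --------------------------------------------

def expressed_opinion_grids(state: LatticeState) -> tuple[np.ndarray, np.ndarray]:
    """Boolean grids of agents currently voicing ``a`` and voicing ``b``."""
    expressing = state.behavior_grid == EXPRESS
    voices_a = expressing & (state.attitude_grid == ATTITUDE_A)
    voices_b = expressing & (state.attitude_grid == ATTITUDE_B)
    return voices_a, voices_b


def neighbor_expressed_counts(state: LatticeState) -> tuple[np.ndarray, np.ndarray]:
    """Per-agent counts of neighbours voicing ``a`` and ``b`` (torus)."""
    voices_a, voices_b = expressed_opinion_grids(state)
    n_a = _four_neighbor_sum(voices_a.astype(np.int8))
    n_b = _four_neighbor_sum(voices_b.astype(np.int8))
    return n_a, n_b


def _four_neighbor_sum(grid: np.ndarray) -> np.ndarray:
    return (np.roll(grid, 1, axis=0) + np.roll(grid, -1, axis=0)
            + np.roll(grid, 1, axis=1) + np.roll(grid, -1, axis=1))


def classify_local_states_grid(n_a: np.ndarray, n_b: np.ndarray) -> np.ndarray:
    """Vectorized five-way classification; returns a grid of label codes."""
    labels = np.full(n_a.shape, PARTIAL_MAJORITY, dtype=np.int8)
    tie = n_a == n_b
    labels[tie] = STALEMATE
    labels[tie & (n_a == 0)] = TOTAL_SILENCE
    labels[(n_a == N_NEIGHBORS) | (n_b == N_NEIGHBORS)] = FULL_MAJORITY
    labels[(n_a > 0) & (n_b > 0) & ~tie] = MAJORITY_WITH_MINORITY
    return labels


def decide_behavior_grid(type_grid: np.ndarray, attitude_grid: np.ndarray,
                         n_a: np.ndarray, n_b: np.ndarray) -> np.ndarray:
    """Vectorized decision rule; returns the next behavior grid (int8).

    Table logic: ties (total silence and stalemate share a row) let only
    reputation seekers speak; majority-with-minority lets only the
    minority-attitude reputation seeker speak; a lone voiced opinion lets
    only the matching-attitude consensus seeker speak.
    """
    tie = n_a == n_b
    contested = (n_a > 0) & (n_b > 0) & ~tie
    majority_is_a = n_a > n_b
    att_matches_majority = (attitude_grid == ATTITUDE_A) == majority_is_a
    is_reputation = type_grid == REPUTATION

    express = np.where(
        tie,
        is_reputation,
        np.where(contested,
                 is_reputation & ~att_matches_majority,
                 ~is_reputation & att_matches_majority),
    )
    return express.astype(np.int8)
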