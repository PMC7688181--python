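import numpy as np
import pytest

import opinionlattice as ol


def naive_step(state: ol.LatticeState) -> np.ndarray:
    """Per-agent reference implementation of one synchronous update.

    Deliberately written as an explicit loop over agents and neighbours,
    independent of the vectorized code path.
    """
    side = state.side
    new = np.zeros((side, side), dtype=np.int8)
    for r in range(side):
        for c in range(side):
            n_a = n_b = 0
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = (r + dr) % side, (c + dc) % side
                if state.behavior_grid[rr, cc] == ol.EXPRESS:
                    if state.attitude_grid[rr, cc] == ol.ATTITUDE_A:
                        n_a += 1
                    else:
                        n_b += 1
            new[r, c] = ol.decide_behavior(
                int(state.type_grid[r, c]),
                int(state.attitude_grid[r, c]),
                ol.LocalCount(n_a, n_b, 4 - n_a - n_b),
            )
    return new


def random_state(rng: np.random.Generator, side: int) -> ol.LatticeState:
    return ol.LatticeState(
        type_grid=rng.integers(0, 2, (side, side)),
        attitude_grid=rng.integers(0, 2, (side, side)),
        behavior_grid=rng.integers(0, 2, (side, side)),
    )


def synthetic_trajectory(symbol_sequence) -> ol.Trajectory:
    """Trajectory whose configurations follow an arbitrary symbol sequence.

    Only the recurrence structure matters to the cycle detectors, so each
    symbol is encoded as a one-byte configuration digest.
    """
    n = len(symbol_sequence)
    zeros = np.zeros((2, 2), dtype=np.int8)
    return ol.Trajectory(
        type_grid=zeros,
        attitude_grid=zeros,
        configs=[bytes([s]) for s in symbol_sequence],
        silent_counts=np.zeros(n, dtype=np.int32),
        delta_e=np.zeros(n, dtype=np.int32),
        local_state_counts=np.zeros((n, 5), dtype=np.int32),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def all_local_counts() -> list[ol.LocalCount]:
    """The 15 admissible neighbour tallies (nonnegative, summing to 4)."""
    return [
        ol.LocalCount(n_a, n_b, 4 - n_a - n_b)
        for n_a in range(5)
        for n_b in range(5 - n_a)
    ]
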