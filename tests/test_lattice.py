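"""Local-state classification, the decision table, and lattice initialization."""

import json
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import opinionlattice as ol
from conftest import all_local_counts

FIXTURE = Path(__file__).parent / "data" / "lattice_4x4_synthetic.json"


def independent_state_predicates(counts: ol.LocalCount) -> dict[int, bool]:
    """The five class predicates written straight from their definitions,
    with the overlap-resolving precedence made explicit."""
    n_a, n_b, _ = counts
    voiced = n_a + n_b
    return {
        ol.TOTAL_SILENCE: voiced == 0,
        ol.STALEMATE: n_a == n_b and voiced > 0,
        ol.FULL_MAJORITY: n_a == 4 or n_b == 4,
        ol.MAJORITY_WITH_MINORITY: n_a > 0 and n_b > 0 and n_a != n_b,
        ol.PARTIAL_MAJORITY: (n_a == 0) != (n_b == 0) and voiced < 4,
    }


def expected_behavior(agent_type: int, attitude: int, counts: ol.LocalCount) -> int:
    """Decision-table oracle: row lookup by (local state, population,
    majority/minority attitude), independent of the implementation."""
    label = ol.classify_local_state(counts)
    if label in (ol.TOTAL_SILENCE, ol.STALEMATE):
        return ol.EXPRESS if agent_type == ol.REPUTATION else ol.SILENT
    majority = ol.ATTITUDE_A if counts.n_a > counts.n_b else ol.ATTITUDE_B
    holds_majority = attitude == majority
    table = {
        # (label-kind, type, holds_majority) -> behavior
        ("contested", ol.CONSENSUS, True): ol.SILENT,
        ("contested", ol.CONSENSUS, False): ol.SILENT,
        ("contested", ol.REPUTATION, True): ol.SILENT,
        ("contested", ol.REPUTATION, False): ol.EXPRESS,
        ("unopposed", ol.CONSENSUS, True): ol.EXPRESS,
        ("unopposed", ol.CONSENSUS, False): ol.SILENT,
        ("unopposed", ol.REPUTATION, True): ol.SILENT,
        ("unopposed", ol.REPUTATION, False): ol.SILENT,
    }
    kind = "contested" if label == ol.MAJORITY_WITH_MINORITY else "unopposed"
    return table[(kind, agent_type, holds_majority)]


class TestLocalStateClassification:
    def test_partition_over_all_15_triples(self):
        """Exactly one class predicate holds for every admissible tally,
        and the classifier returns that class."""
        triples = all_local_counts()
        assert len(triples) == 15
        for counts in triples:
            predicates = independent_state_predicates(counts)
            true_labels = [label for label, holds in predicates.items() if holds]
            assert len(true_labels) == 1, counts
            assert ol.classify_local_state(counts) == true_labels[0]

    @pytest.mark.parametrize("counts, label", [
        ((0, 0, 4), ol.TOTAL_SILENCE),
        ((2, 2, 0), ol.STALEMATE),
        ((1, 1, 2), ol.STALEMATE),
        ((2, 1, 1), ol.MAJORITY_WITH_MINORITY),
        ((3, 0, 1), ol.PARTIAL_MAJORITY),
        ((0, 4, 0), ol.FULL_MAJORITY),
    ])
    def test_named_examples(self, counts, label):
        assert ol.classify_local_state(ol.LocalCount(*counts)) == label

    @pytest.mark.parametrize("bad", [(1, 1, 1), (5, 0, -1), (3, 3, -2)])
    def test_invalid_tallies_rejected(self, bad):
        with pytest.raises(ValueError):
            ol.classify_local_state(ol.LocalCount(*bad))

    def test_vectorized_classifier_matches_scalar(self):
        n_a = np.array([c.n_a for c in all_local_counts()])
        n_b = np.array([c.n_b for c in all_local_counts()])
        expected = [ol.classify_local_state(c) for c in all_local_counts()]
        assert ol.classify_local_states_grid(n_a, n_b).tolist() == expected


class TestDecisionRule:
    def test_exhaustive_60_inputs_match_table(self):
        """All 2 types x 2 attitudes x 15 tallies agree with the row-lookup
        oracle; the rule is total and deterministic."""
        checked = 0
        for agent_type in (ol.CONSENSUS, ol.REPUTATION):
            for attitude in (ol.ATTITUDE_A, ol.ATTITUDE_B):
                for counts in all_local_counts():
                    got = ol.decide_behavior(agent_type, attitude, counts)
                    assert got in (ol.SILENT, ol.EXPRESS)
                    assert got == expected_behavior(agent_type, attitude, counts)
                    checked += 1
        assert checked == 60

    @pytest.mark.parametrize("agent_type, attitude, counts, behavior", [
        (ol.REPUTATION, ol.ATTITUDE_A, (0, 0, 4), ol.EXPRESS),
        (ol.REPUTATION, ol.ATTITUDE_B, (0, 0, 4), ol.EXPRESS),
        (ol.CONSENSUS, ol.ATTITUDE_A, (3, 1, 0), ol.SILENT),
        (ol.REPUTATION, ol.ATTITUDE_B, (3, 1, 0), ol.EXPRESS),
        (ol.CONSENSUS, ol.ATTITUDE_A, (2, 0, 2), ol.EXPRESS),
        (ol.CONSENSUS, ol.ATTITUDE_B, (4, 0, 0), ol.SILENT),
    ])
    def test_named_examples(self, agent_type, attitude, counts, behavior):
        assert ol.decide_behavior(agent_type, attitude, ol.LocalCount(*counts)) == behavior

    def test_opinion_relabeling_symmetry(self):
        """Swapping the roles of a and b everywhere leaves every decision
        unchanged."""
        for agent_type in (ol.CONSENSUS, ol.REPUTATION):
            for attitude in (ol.ATTITUDE_A, ol.ATTITUDE_B):
                for counts in all_local_counts():
                    flipped_attitude = 1 - attitude
                    flipped = ol.LocalCount(counts.n_b, counts.n_a, counts.n_silent)
                    assert (ol.decide_behavior(agent_type, attitude, counts)
                            == ol.decide_behavior(agent_type, flipped_attitude, flipped))


class TestFixtureLattice:
    def test_hand_derived_cases(self):
        """Hand-worked neighbour tallies, labels and next-step behaviors on
        the shipped 4x4 fixture all agree with the implementation."""
        fixture = json.loads(FIXTURE.read_text())
        state = ol.LatticeState(
            np.array(fixture["type_grid"]),
            np.array(fixture["attitude_grid"]),
            np.array(fixture["behavior_grid"]),
        )
        n_a, n_b = ol.neighbor_expressed_counts(state)
        stepped = ol.synchronous_step(state)
        for case in fixture["cases"]:
            r, c = case["cell"]
            assert (n_a[r, c], n_b[r, c]) == (case["n_a"], case["n_b"]), case
            counts = ol.LocalCount(int(n_a[r, c]), int(n_b[r, c]),
                                   4 - int(n_a[r, c]) - int(n_b[r, c]))
            label = ol.LOCAL_STATE_NAMES[ol.classify_local_state(counts)]
            assert label == case["label"], case
            assert stepped.behavior_grid[r, c] == case["next_behavior"], case


class TestInitLattice:
    @pytest.mark.parametrize("side, density, expected", [
        (10, 0.65, 65), (10, 0.0, 0), (10, 1.0, 100), (4, 0.5, 8), (5, 0.33, 8),
    ])
    def test_exact_reputation_count(self, side, density, expected):
        config = ol.SimulationConfig(lattice_side=side, r_density=density, seed=3)
        state = ol.init_lattice(config)
        assert int((state.type_grid == ol.REPUTATION).sum()) == expected

    def test_degenerate_densities(self):
        all_c = ol.init_lattice(ol.SimulationConfig(lattice_side=6, r_density=0.0, seed=1))
        assert (all_c.type_grid == ol.CONSENSUS).all()
        all_r = ol.init_lattice(ol.SimulationConfig(lattice_side=6, r_density=1.0, seed=1))
        assert (all_r.type_grid == ol.REPUTATION).all()

    def test_seed_reproducibility(self):
        config = ol.SimulationConfig(lattice_side=8, r_density=0.4, seed=99)
        a, b = ol.init_lattice(config), ol.init_lattice(config)
        assert np.array_equal(a.type_grid, b.type_grid)
        assert np.array_equal(a.attitude_grid, b.attitude_grid)
        assert np.array_equal(a.behavior_grid, b.behavior_grid)
        other = ol.init_lattice(config, seed=100)
        assert not (np.array_equal(a.type_grid, other.type_grid)
                    and np.array_equal(a.behavior_grid, other.behavior_grid))

    def test_extreme_probabilities(self):
        state = ol.init_lattice(ol.SimulationConfig(
            lattice_side=5, p_attitude_a=1.0, p_initial_express=0.0, seed=0))
        assert (state.attitude_grid == ol.ATTITUDE_A).all()
        assert (state.behavior_grid == ol.SILENT).all()

    @pytest.mark.parametrize("field, value", [
        ("lattice_side", 1),
        ("r_density", 1.3),
        ("p_attitude_a", -0.2),
        ("p_initial_express", 2.0),
        ("max_steps", 0),
        ("epsilon_correspondence", -0.01),
    ])
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            ol.SimulationConfig(**{field: value})

    @given(side=st.integers(2, 12), density=st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_reputation_count_rounds_density(self, side, density):
        config = ol.SimulationConfig(lattice_side=side, r_density=density, seed=0)
        state = ol.init_lattice(config)
        n = side * side
        assert int((state.type_grid == ol.REPUTATION).sum()) == int(np.floor(density * n + 0.5))
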