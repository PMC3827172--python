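import itertools

import numpy as np
import pytest

from ndm.landscape import CellCoord, homogeneous_landscape
from ndm.persistence import ConstantPersistence, SpeciesSpec
from ndm.simulator import (
    Community,
    OccupancyState,
    SimulationConfig,
    apply_richness_cap,
    empty_occupancy,
    full_occupancy,
    occupancy_probability,
    occupancy_update_prob,
    replicate_final_states,
    run,
    step,
)


def constant_species(n, p_e=0.8, p_max=1.0, d_max=1):
    return [
        SpeciesSpec(f"s{i}", p_max, ConstantPersistence(p_e), d_max=d_max)
        for i in range(n)
    ]


def two_cell_markov_occupancy(p_e, p_max, years):
    """Oracle: exact 4-state chain for 1 species on 2 adjacent cells.

    States are (left occupied, right occupied); the synchronous update gives
    independent per-cell Bernoulli transitions whose probabilities depend
    only on the current joint state.  Returns the expected per-cell
    occupancy probabilities after ``years`` steps from full occupancy.
    """
    states = list(itertools.product([0, 1], repeat=2))

    def cell_prob(own, other):
        if own:
            return p_e
        return (p_max if other else 0.0) * p_e

    T = np.zeros((4, 4))
    for i, s in enumerate(states):
        p = [cell_prob(s[0], s[1]), cell_prob(s[1], s[0])]
        for j, t in enumerate(states):
            T[i, j] = np.prod([q if b else 1 - q for q, b in zip(p, t)])
    dist = np.zeros(4)
    dist[states.index((1, 1))] = 1.0
    for _ in range(years):
        dist = dist @ T
    occ0 = sum(dist[i] for i, s in enumerate(states) if s[0])
    occ1 = sum(dist[i] for i, s in enumerate(states) if s[1])
    return occ0, occ1


class TestUpdateProbability:
    def test_three_branches(self):
        L = homogeneous_landscape(5, 5)
        s = constant_species(1, p_e=0.8, p_max=0.5, d_max=1)[0]
        occ = np.zeros(L.shape, bool)
        occ[2, 2] = True
        # present: persistence branch
        assert occupancy_update_prob(s, CellCoord(2, 2), occ, L) == pytest.approx(0.8)
        # absent with one adjacent source: immigration x persistence
        assert occupancy_update_prob(s, CellCoord(2, 3), occ, L) == pytest.approx(0.4)
        # absent, no source in range
        assert occupancy_update_prob(s, CellCoord(0, 0), occ, L) == 0.0


class TestRichnessCapSort:
    def test_under_cap_untouched(self):
        rng = np.random.default_rng(0)
        cand = [("a", 0.9), ("b", 0.5), ("c", 0.2)]
        assert apply_richness_cap(cand, 3, rng) == {"a", "b", "c"}

    def test_sorted_by_persistence(self):
        rng = np.random.default_rng(0)
        cand = [("lo", 0.5), ("hi", 0.9), ("mid", 0.7)]
        assert apply_richness_cap(cand, 2, rng) == {"hi", "mid"}

    def test_tied_candidates_drawn_uniformly(self):
        """4 equal candidates, cap 2: each of the 6 pairs kept ~1/6 of the time."""
        rng = np.random.default_rng(123)
        cand = [(s, 0.6) for s in "abcd"]
        counts: dict[frozenset, int] = {}
        n = 10_000
        for _ in range(n):
            kept = frozenset(apply_richness_cap(cand, 2, rng))
            counts[kept] = counts.get(kept, 0) + 1
        assert len(counts) == 6
        for k, v in counts.items():
            # binomial(n, 1/6) 4-sigma band
            assert abs(v / n - 1 / 6) < 4 * np.sqrt((1 / 6) * (5 / 6) / n), k

    def test_vectorised_step_never_exceeds_cap(self):
        L = homogeneous_landscape(6, 6, cap=3)
        community = Community(constant_species(8, p_e=0.9, d_max=2), L)
        state = full_occupancy(L, 8)
        rng = np.random.default_rng(5)
        for _ in range(10):
            state = step(state, community, rng)
            assert state.richness().max() <= 3

    def test_cap_keeps_best_persisters(self):
        """With distinct persistence, the survivors of a capped cell are the top ranked."""
        L = homogeneous_landscape(1, 1, cap=2)
        species = [
            SpeciesSpec(f"s{i}", 1.0, ConstantPersistence(p), d_max=1)
            for i, p in enumerate([1.0, 1.0, 1.0])
        ]
        # all three certain to persist; cap 2 forces exactly 2 survivors
        community = Community(species, L)
        state = full_occupancy(L, 3)
        out = step(state, community, np.random.default_rng(0))
        assert out.presence[:, 0, 0].sum() == 2


class TestStepDynamics:
    def test_full_occupancy_absorbing(self):
        L = homogeneous_landscape(4, 4, cap=None)
        community = Community(constant_species(2, p_e=1.0, p_max=1.0), L)
        state = full_occupancy(L, 2)
        out = step(state, community, np.random.default_rng(1))
        assert np.array_equal(out.presence, state.presence)
        assert out.time == 1

    def test_empty_stays_empty(self):
        L = homogeneous_landscape(4, 4)
        community = Community(constant_species(1, p_e=0.9, p_max=0.0), L)
        out = step(empty_occupancy(L, 1), community, np.random.default_rng(1))
        assert not out.presence.any()

    def test_nonviable_never_occupied(self):
        viable = np.ones((5, 5), bool)
        viable[2, :] = False
        L = homogeneous_landscape(5, 5, viable=viable)
        community = Community(constant_species(2, p_e=1.0, d_max=2), L)
        state = full_occupancy(L, 2)
        rng = np.random.default_rng(2)
        for _ in range(5):
            state = step(state, community, rng)
            assert not state.presence[:, ~viable].any()

    def test_dispersal_crosses_nonviable_gap(self):
        """A non-viable strip is dead ground but not a dispersal barrier."""
        viable = np.ones((1, 3), bool)
        viable[0, 1] = False
        L = homogeneous_landscape(1, 3, viable=viable)
        community = Community(constant_species(1, p_e=1.0, p_max=1.0, d_max=2), L)
        state = empty_occupancy(L, 1)
        state.presence[0, 0, 0] = True
        out = step(state, community, np.random.default_rng(0))
        assert out.presence[0, 0, 2]  # colonised across the gap at d=2

    def test_run_composition_and_determinism(self):
        L = homogeneous_landscape(6, 6)
        community = Community(constant_species(3, p_e=0.8, d_max=2), L)
        init = full_occupancy(L, 3)
        zero = run(init, SimulationConfig(years=0, seed=9), community)
        assert np.array_equal(zero.presence, init.presence)
        a = run(init, SimulationConfig(years=7, seed=9), community)
        b = run(init, SimulationConfig(years=7, seed=9), community)
        assert np.array_equal(a.presence, b.presence)
        one = run(init, SimulationConfig(years=1, seed=9), community)
        manual = step(init, community, np.random.default_rng(9))
        assert np.array_equal(one.presence, manual.presence)

    def test_trajectory_recording(self):
        L = homogeneous_landscape(3, 3)
        community = Community(constant_species(1, p_e=0.7), L)
        final, traj = run(
            full_occupancy(L, 1),
            SimulationConfig(years=4, seed=0, record_trajectory=True),
            community,
        )
        assert len(traj) == 5
        assert traj[-1].time == final.time == 4

    def test_extinction_without_immigration(self):
        """p_max=0 and P_E<1: every replicate goes extinct (no rescue effect)."""
        L = homogeneous_landscape(4, 4)
        community = Community(constant_species(1, p_e=0.5, p_max=0.0), L)
        init = full_occupancy(L, 1)
        cfg = SimulationConfig(years=60, replicates=20, seed=11)
        for final in replicate_final_states(init, cfg, community):
            assert not final.presence.any()


class TestMonteCarloAgainstClosedForms:
    def test_isolated_cell_survival(self):
        """Isolated occupied cell: survival to t=3 is P_E^3 = 0.512."""
        L = homogeneous_landscape(1, 1)
        community = Community(constant_species(1, p_e=0.8), L)
        init = full_occupancy(L, 1)
        n = 20_000
        field = occupancy_probability(init, SimulationConfig(3, n, seed=21), community)
        p_hat = field.probability[0, 0, 0]
        assert abs(p_hat - 0.512) < 3 * np.sqrt(0.512 * 0.488 / n)

    def test_two_cell_markov_chain(self):
        """Replicate means match the exact 4-state transition-matrix iteration."""
        p_e, p_max, years = 0.7, 0.6, 8
        L = homogeneous_landscape(1, 2)
        community = Community(constant_species(1, p_e=p_e, p_max=p_max, d_max=1), L)
        init = full_occupancy(L, 1)
        n = 20_000
        field = occupancy_probability(init, SimulationConfig(years, n, seed=33), community)
        exact = two_cell_markov_occupancy(p_e, p_max, years)
        for cell in (0, 1):
            mc = field.probability[0, 0, cell]
            se = np.sqrt(exact[cell] * (1 - exact[cell]) / n)
            assert abs(mc - exact[cell]) < 4 * se

    def test_field_trivial_limits(self):
        viable = np.ones((3, 3), bool)
        viable[0, 0] = False
        L = homogeneous_landscape(3, 3, viable=viable, cap=None)
        community = Community(constant_species(2, p_e=1.0, p_max=1.0), L)
        init = full_occupancy(L, 2)
        field = occupancy_probability(init, SimulationConfig(5, 10, seed=1), community)
        assert np.all(field.probability[:, viable] == 1.0)
        assert np.all(field.probability[:, ~viable] == 0.0)


class TestReplicateStreams:
    def test_replicates_differ_but_rerun_identical(self):
        L = homogeneous_landscape(5, 5)
        community = Community(constant_species(2, p_e=0.8, d_max=2), L)
        init = full_occupancy(L, 2)
        cfg = SimulationConfig(years=10, replicates=4, seed=77)
        finals_a = [s.presence.copy() for s in replicate_final_states(init, cfg, community)]
        finals_b = [s.presence.copy() for s in replicate_final_states(init, cfg, community)]
        assert all(np.array_equal(a, b) for a, b in zip(finals_a, finals_b))
        assert any(
            not np.array_equal(finals_a[i], finals_a[j])
            for i in range(4)
            for j in range(i + 1, 4)
        )
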