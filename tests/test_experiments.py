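import numpy as np
import pytest

from ndm.experiments import (
    SCALE_PARAMS,
    VirtualCommunitySpec,
    generate_virtual_community,
    generate_vanera_like_fixture,
    run_island_experiment,
    run_matrix_destruction,
    run_middomain_experiment,
)
from ndm.landscape import homogeneous_landscape
from ndm.persistence import ConstantPersistence, SpeciesSpec
from ndm.simulator import SimulationConfig

FAST = SimulationConfig(years=15, replicates=5, seed=0)


class TestVirtualCommunity:
    def test_degenerate_persistence_range(self):
        spec = VirtualCommunitySpec(n_species=5, persistence_range=(0.8, 0.8), seed=1)
        comm = generate_virtual_community(spec)
        assert all(s.persistence.p == pytest.approx(0.8) for s in comm)

    def test_draws_match_declared_ranges(self):
        spec = VirtualCommunitySpec(seed=2)
        comm = generate_virtual_community(spec)
        assert len(comm) == 30
        assert all(0.7 <= s.persistence.p <= 0.9 for s in comm)
        assert all(1 <= s.d_max <= 6 for s in comm)
        assert all(s.p_max == spec.p_max for s in comm)

    def test_persistence_mean_law_of_large_numbers(self):
        rng = np.random.default_rng(3)
        spec = VirtualCommunitySpec(n_species=30)
        vals = [
            s.persistence.p
            for _ in range(300)
            for s in generate_virtual_community(spec, rng)
        ]
        n = len(vals)
        sd = (0.9 - 0.7) / np.sqrt(12)
        assert abs(np.mean(vals) - 0.8) < 3 * sd / np.sqrt(n)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            VirtualCommunitySpec(persistence_range=(0.9, 0.7))
        with pytest.raises(ValueError):
            VirtualCommunitySpec(d_max_range=(0, 3))


class TestValleyFixture:
    @pytest.fixture(scope="class")
    def fixture(self):
        return generate_vanera_like_fixture(11)

    def test_viable_cell_count(self, fixture):
        L, _, _ = fixture
        assert (L.n_rows, L.n_cols) == (19, 24)
        assert L.n_viable == 214

    def test_pine_fraction(self, fixture):
        L, _, _ = fixture
        pine = np.isin(L.habitat, ["dense_pine", "clear_pine"]) & L.viable
        assert 0.25 <= pine.sum() / L.n_viable <= 0.35

    def test_caps_table(self, fixture):
        L, _, _ = fixture
        assert L.richness_cap["lowland"] == 17
        assert L.richness_cap["heath"] == 16
        assert L.richness_cap["grassland"] == 11
        assert L.richness_cap["dense_pine"] == 14
        assert L.richness_cap["clear_pine"] == 14

    def test_all_habitats_present(self, fixture):
        L, _, _ = fixture
        present = {str(h) for h in L.habitat[L.viable]}
        assert present == {"lowland", "heath", "grassland", "dense_pine", "clear_pine"}

    def test_community_and_observations(self, fixture):
        L, species, obs = fixture
        assert len(species) == 45
        assert obs.y.shape == (45, 19, 24)
        assert not obs.y[:, ~L.viable].any()
        # the snapshot respects every habitat's richness cap
        rich = obs.y.sum(axis=0)
        caps = L.cap_grid()
        assert np.all(rich[L.viable] <= caps[L.viable])

    def test_reproducible(self):
        a = generate_vanera_like_fixture(4)
        b = generate_vanera_like_fixture(4)
        assert np.array_equal(a[0].viable, b[0].viable)
        assert np.array_equal(a[2].y, b[2].y)


class TestIsland:
    def test_richness_zero_beyond_dispersal_range(self):
        """A 1-cell island beyond every d_max gets no immigrants and empties out.

        With P_E < 1 and neither external nor within-island rescue, extinction
        is certain; larger islands can self-rescue at local-scale p_max = 1.
        """
        rep = run_island_experiment(
            1.0, 12.0, "local", SimulationConfig(years=60, replicates=3, seed=1)
        )
        assert rep.summary["island_total_richness"] == 0.0

    def test_adjacent_island_tracks_mainland(self):
        rep = run_island_experiment(
            6.0, 1.0, "local", SimulationConfig(years=20, replicates=5, seed=2)
        )
        diff = (
            rep.summary["mainland_mean_cell_richness"]
            - rep.summary["island_mean_cell_richness"]
        )
        assert abs(diff) < 3.0

    def test_geometry_and_units(self):
        rep = run_island_experiment(2400.0, 80.0, "regional", FAST)
        assert rep.params["island_cells"] == 6
        assert rep.params["distance_cells"] == 4
        assert SCALE_PARAMS["regional"]["cell_side_km"] == 20.0

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            run_island_experiment(6.0, 4.0, "continental", FAST)

    def test_reproducible(self):
        a = run_island_experiment(6.0, 2.0, "local", FAST)
        b = run_island_experiment(6.0, 2.0, "local", FAST)
        assert a.per_replicate.equals(b.per_replicate)


class TestMidDomain:
    def test_report_structure_and_symmetry(self):
        rep = run_middomain_experiment(
            "regional", SimulationConfig(years=20, replicates=4, seed=3), grid_size=20,
            centre_size=6, edge_width=3,
        )
        assert rep.richness_map.shape == (20, 20)
        # homogeneous isotropic setup: map statistically symmetric under rotation
        m = rep.richness_map
        assert abs(m.mean() - np.rot90(m).mean()) < 1e-9
        corr = np.corrcoef(m.ravel(), np.rot90(m, 2).ravel())[0, 1]
        assert corr > 0.0

    def test_centre_edge_columns(self):
        rep = run_middomain_experiment(
            "local", SimulationConfig(years=10, replicates=3, seed=4), grid_size=16,
            centre_size=4, edge_width=2,
        )
        assert {"centre_mean_richness", "edge_mean_richness", "centre_minus_edge"} <= set(
            rep.per_replicate.columns
        )


class TestMatrixDestruction:
    def _landscape(self):
        L = homogeneous_landscape(8, 8, habitat="forest", cap=None)
        return L

    def _species(self, n=3):
        return [
            SpeciesSpec(f"s{i}", 1.0, ConstantPersistence(0.8), d_max=2)
            for i in range(n)
        ]

    def test_all_forest_is_a_noop(self):
        L = self._landscape()
        forest = L.viable.copy()
        rep = run_matrix_destruction(L, self._species(), forest, FAST)
        s = rep.summary
        assert s["forest_total_richness_before"] == s["forest_total_richness_after"]
        assert s["forest_mean_cell_richness_before"] == pytest.approx(
            s["forest_mean_cell_richness_after"]
        )

    def test_destruction_never_adds_species(self):
        L, species, _ = generate_vanera_like_fixture(5)
        forest = np.isin(L.habitat, ["dense_pine", "clear_pine"]) & L.viable
        rep = run_matrix_destruction(L, species, forest, FAST)
        s = rep.summary
        assert s["forest_total_richness_after"] <= s["forest_total_richness_before"]

    def test_matrix_specialists_collapse(self):
        """Species persisting poorly in forest lose most forest occurrence once sources go."""
        L, species, _ = generate_vanera_like_fixture(6)
        forest = np.isin(L.habitat, ["dense_pine", "clear_pine"]) & L.viable
        cfg = SimulationConfig(years=50, replicates=10, seed=9)
        rep = run_matrix_destruction(L, species, forest, cfg)
        tab = rep.species_table.set_index("species_id")
        from ndm.persistence import persistence_field

        specialists = [
            s.species_id
            for s in species
            if persistence_field(s.persistence, L)[forest].max() < 0.1
        ]
        assert specialists  # the fixture always contains matrix birds
        before = tab.loc[specialists, "forest_occurrence_before"]
        after = tab.loc[specialists, "forest_occurrence_after"]
        assert after.sum() <= 0.5 * before.sum()

    def test_empty_forest_mask(self):
        L = self._landscape()
        with pytest.raises(ValueError):
            run_matrix_destruction(L, self._species(), np.zeros(L.shape, bool), FAST)

    def test_mask_outside_viable(self):
        L = homogeneous_landscape(4, 4, viable=np.eye(4, dtype=bool))
        bad = np.ones(L.shape, bool)
        with pytest.raises(ValueError):
            run_matrix_destruction(L, self._species(), bad, FAST)
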