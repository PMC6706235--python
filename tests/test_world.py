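"""Grid topology, scheduler, offspring placement, event resolution, engines."""

import numpy as np
import pytest
from scipy import stats

from unicell.errors import ConfigurationError, SimulationStateError, UsageError
from unicell.genome import PCD, Genome, count_pcd_sites, make_ancestor
from unicell.world import SimulationConfig, World

from conftest import (all_inert_genome, check_random_pcd_snapshot,
                      genome_with, make_world, random_genome,
                      toroidal_chebyshev)


class TestConfig:
    def test_defaults_match_study_conditions(self):
        cfg = SimulationConfig()
        assert (cfg.grid_width, cfg.grid_height) == (60, 60)
        assert cfg.genome_length == 100 and cfg.mu == 0.0075
        assert cfg.p_success == 0.05 and cfg.effect_factor == 5.0
        assert cfg.radius == 2 and cfg.cycles_per_organism_per_update == 30
        assert cfg.updates == 60_000

    @pytest.mark.parametrize("bad", [
        {"kil": 101},
        {"mu": -0.1},
        {"effect_factor": 0.5},
        {"mode": "sideways"},
        {"grid_width": 2},
        {"radius": 40},
    ])
    def test_out_of_range_values_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**bad)


class TestInjection:
    def test_ancestor_population_merit_and_no_pcd(self):
        w = make_world(grid_width=60, grid_height=60)
        org = w.inject_ancestor()
        assert w.population == 1
        assert org.merit == 100.0  # merit equals genome length
        assert count_pcd_sites(org.genome) == 0

    def test_occupied_world_rejected(self):
        w = make_world()
        w.inject_ancestor()
        with pytest.raises(UsageError):
            w.inject_ancestor()


class TestNeighborhood:
    def test_radius_two_is_24_cells(self):
        w = make_world(grid_width=60, grid_height=60)
        cells = w.neighborhood((30, 30), 2)
        assert len(cells) == len(set(cells)) == 24

    def test_radius_zero_empty(self):
        assert make_world().neighborhood((3, 3), 0) == []

    def test_corner_wraps_to_24_distinct_cells(self):
        w = make_world(grid_width=60, grid_height=60)
        cells = w.neighborhood((0, 0), 2)
        assert len(cells) == len(set(cells)) == 24
        assert all(0 <= x < 60 and 0 <= y < 60 for x, y in cells)

    @pytest.mark.parametrize("center", [(0, 0), (6, 3), (3, 6), (5, 5)])
    def test_matches_toroidal_chebyshev_oracle(self, center):
        w = make_world(grid_width=7, grid_height=9)
        got = set(w.neighborhood(center, 2))
        expect = {(x, y) for x in range(7) for y in range(9)
                  if (x, y) != center
                  and toroidal_chebyshev(center, (x, y), 7, 9) <= 2}
        assert got == expect

    def test_wrap_collision_rejected(self):
        w = make_world(grid_width=5, grid_height=5)
        with pytest.raises(ConfigurationError):
            w.neighborhood((2, 2), 3)


class TestPlaceOffspring:
    def test_full_neighbourhood_keeps_population_constant(self):
        w = make_world(grid_width=5, grid_height=5)
        for x in range(5):
            for y in range(5):
                w.place(all_inert_genome(), (x, y))
        w.place_offspring((2, 2), all_inert_genome(), 100.0)
        assert w.population == 25  # one death, one birth

    def test_empty_neighbourhood_grows_population(self):
        w = make_world()
        w.place(all_inert_genome(), (3, 3))
        w.place_offspring((3, 3), all_inert_genome(), 100.0)
        assert w.population == 2

    def test_destination_uniform_over_eight_neighbours(self):
        w = make_world(grid_width=9, grid_height=9, seed=17)
        parent = w.place(all_inert_genome(), (4, 4))
        n = 80_000
        counts = {}
        for _ in range(n):
            child = w.place_offspring((4, 4), all_inert_genome(), 100.0)
            counts[child.location] = counts.get(child.location, 0) + 1
            if child.location != (4, 4):
                w._kill(child.cell)
        assert parent.alive
        assert set(counts) == set(w.neighborhood((4, 4), 1))
        sigma = np.sqrt(n * (1 / 8) * (7 / 8))
        for c in counts.values():
            assert abs(c - n / 8) < 3 * sigma


class TestResolvePcdEvent:
    def _clone_block(self, mode, kil, factor=5.0):
        w = make_world(grid_width=7, grid_height=7, mode=mode, kil=kil,
                       effect_factor=factor)
        g = genome_with(pcd_at=(0,))
        for (x, y) in [(3, 3)] + w.neighborhood((3, 3), 2):
            w.place(g, (x, y))
        return w

    def test_direct_clonal_block_benefits_all_24(self):
        w = self._clone_block("direct", kil=0)
        ev = w.resolve_pcd_event((3, 3))
        assert (ev.n_kin_affected, ev.n_nonkin_affected) == (24, 0)
        assert ev.n_cheater_kin == 0  # every clone carries the instruction
        assert w.organism_at((3, 3)) is None and w.population == 24
        mults = [o.offspring_multiplier for o in w.organisms()]
        assert mults == [5.0] * 24

    def test_indirect_clonal_block_affects_nobody(self):
        w = self._clone_block("indirect", kil=0)
        w.resolve_pcd_event((3, 3))
        assert all(o.offspring_multiplier == 1.0 for o in w.organisms())

    def test_partition_of_mixed_neighbourhood(self):
        w = make_world(grid_width=7, grid_height=7, mode="direct", kil=3)
        focal = genome_with(pcd_at=(0,))
        near = focal.copy()
        near.sites[1:3] = 5  # HD 2: kin
        far = focal.copy()
        far.sites[1:6] = 5  # HD 5: nonkin
        cells = w.neighborhood((3, 3), 2)
        w.place(focal, (3, 3))
        for loc in cells[:10]:
            w.place(near.copy(), loc)
        for loc in cells[10:]:
            w.place(far.copy(), loc)
        ev = w.resolve_pcd_event((3, 3))
        assert (ev.n_kin_affected, ev.n_nonkin_affected) == (10, 14)
        assert ev.n_kin_affected + ev.n_nonkin_affected == 24

    def test_cheater_kin_are_counted(self):
        w = make_world(grid_width=7, grid_height=7, mode="direct", kil=3)
        focal = genome_with(pcd_at=(0,))
        cheater = genome_with(pcd_at=())  # kin by distance, no PCD gene
        w.place(focal, (3, 3))
        for loc in w.neighborhood((3, 3), 1)[:5]:
            w.place(focal.copy() if loc[0] % 2 else cheater.copy(), loc)
        ev = w.resolve_pcd_event((3, 3))
        carriers = sum(count_pcd_sites(o.genome) > 0 for o in w.organisms())
        assert ev.n_cheater_kin == ev.n_kin_affected - carriers

    def test_control_records_classification_without_effect(self):
        w = self._clone_block("direct", kil=0, factor=1.0)
        ev = w.resolve_pcd_event((3, 3))
        assert ev.n_kin_affected == 24
        assert all(o.offspring_multiplier == 1.0 for o in w.organisms())

    def test_empty_focal_cell_is_an_error(self):
        w = make_world()
        with pytest.raises(SimulationStateError):
            w.resolve_pcd_event((1, 1))

    def test_counts_match_bruteforce_on_random_snapshots(self):
        """Independent partition of the 5x5 block on randomized toy worlds."""
        for case in range(200):
            check_random_pcd_snapshot(case)


class TestScheduler:
    def test_single_organism_receives_whole_budget(self):
        w = make_world()
        org = w.place(all_inert_genome(), (3, 3))
        w.step_update()
        assert org.cycles_executed == 30

    def test_equal_merits_share_cycles_evenly(self):
        w = make_world(grid_width=5, grid_height=5, seed=2)
        for x in range(5):
            w.place(all_inert_genome(), (x, 0))
        for _ in range(200):
            w.step_update()
        counts = np.array([o.cycles_executed for o in w.organisms()])
        assert counts.sum() == 5 * 30 * 200
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_cycle_share_proportional_to_merit(self):
        w = make_world(grid_width=5, grid_height=5, seed=4, engine="fast")
        low = w.place(all_inert_genome(), (0, 0), merit=100.0)
        high = w.place(all_inert_genome(), (3, 3), merit=500.0)
        w.run(updates=2_000, record=False)
        n = 2 * 30 * 2_000
        share = low.cycles_executed / n
        sigma = np.sqrt((1 / 6) * (5 / 6) / n)
        assert abs(share - 1 / 6) < 3 * sigma


class TestEnginesAndDeterminism:
    EVOLVING = dict(grid_width=12, grid_height=12, mu=0.02, mode="direct",
                    kil=3, effect_factor=5.0, seed=33, updates=80)

    def test_fast_and_reference_engines_are_bit_identical(self):
        wa = World(SimulationConfig(engine="reference", **self.EVOLVING))
        wb = World(SimulationConfig(engine="fast", **self.EVOLVING))
        for w in (wa, wb):
            w.inject_ancestor()
            w.run()
        assert wa.events == wb.events
        assert wa.update == wb.update and wa.population == wb.population
        for name in ("genomes", "alive", "merit", "offspring_multiplier",
                     "ip", "copy_progress", "pcd_attempts", "births",
                     "cycles_executed", "ids"):
            assert np.array_equal(getattr(wa, name), getattr(wb, name)), name
        assert wa.rng.bit_generator.state == wb.rng.bit_generator.state

    def test_identical_seed_reproduces_run_exactly(self):
        runs = []
        for _ in range(2):
            w = World(SimulationConfig(engine="fast", **self.EVOLVING))
            w.inject_ancestor()
            w.run()
            runs.append(w)
        a, b = runs
        assert a.events == b.events
        assert a.timeseries_df().equals(b.timeseries_df())
        assert a.dump_df().equals(b.dump_df())

    def test_occupancy_invariant_after_updates(self):
        w = World(SimulationConfig(engine="fast", **self.EVOLVING))
        w.inject_ancestor()
        w.run()
        assert w.population == int(w.alive.sum())
        assert 1 <= w.population <= 12 * 12

    def test_event_counts_bounded_by_neighbourhood(self):
        w = World(SimulationConfig(engine="fast", **self.EVOLVING,
                                   ).with_(updates=300, p_success=0.2))
        w.inject_ancestor()
        w.run()
        assert len(w.events) > 0
        for ev in w.events:
            assert ev.n_kin_affected + ev.n_nonkin_affected <= 24
            assert ev.n_cheater_kin <= ev.n_kin_affected

    def test_extinction_flags_and_halts_the_run(self):
        w = make_world(p_success=1.0)
        w.place(genome_with(pcd_at=(0,)), (3, 3))
        w.run(updates=10, record=False)
        assert w.extinct and w.population == 0
        assert len(w.events) == 1
        with pytest.raises(SimulationStateError):
            w.step_update()
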