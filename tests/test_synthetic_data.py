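"""Generators: scripted landscapes, occurrence sampling, Yule trees, fossils."""

import numpy as np
import pytest
from scipy import stats

from paleorange import synthetic_data as sd
from paleorange.fragmentation import label_components


class TestMakeEnvSeries:
    def test_no_events_keeps_range_connected(self):
        syn = sd.make_env_series(n_slices=4, shape=(20, 20), seed=0)
        for m in syn.truth_masks:
            assert label_components(m).n_components == 1

    def test_barrier_splits_truth_at_scripted_slice(self):
        ev = sd.ScriptedEvent("barrier", 2, 5, rows=(0, 20), cols=(9, 12))
        syn = sd.make_env_series(
            n_slices=6, shape=(20, 20), seed=0,
            bumps=[((10, 10), 7.0, 1.0)], events=[ev],
        )
        counts = [label_components(m).n_components for m in syn.truth_masks]
        assert counts[:2] == [1, 1]
        assert all(c == 2 for c in counts[2:])

    def test_corridor_pulse_active_only_in_window(self):
        ev = sd.ScriptedEvent("corridor_pulse", 4, 4, rows=(9, 11), cols=(5, 15))
        syn = sd.make_env_series(
            n_slices=6, shape=(20, 20), seed=0,
            bumps=[((10, 3), 3.0, 1.0), ((10, 17), 3.0, 1.0)], events=[ev],
        )
        gap = (slice(9, 11), slice(8, 12))
        for k, m in enumerate(syn.truth_masks):
            assert m[gap].any() == (k == 4)

    def test_contradictory_events_rejected(self):
        a = sd.ScriptedEvent("barrier", 1, 5, rows=(0, 10), cols=(4, 6))
        b = sd.ScriptedEvent("corridor_pulse", 2, 3, rows=(0, 10), cols=(5, 8))
        with pytest.raises(ValueError, match="contradictory"):
            sd.make_env_series(n_slices=6, shape=(10, 10), seed=0, events=[a, b])

    def test_pure_function_of_seed(self):
        a = sd.make_env_series(n_slices=3, shape=(12, 12), seed=9)
        b = sd.make_env_series(n_slices=3, shape=(12, 12), seed=9)
        for sa, sb in zip(a.series, b.series):
            for name in sa.variables:
                assert np.array_equal(
                    sa.variables[name].values, sb.variables[name].values
                )


class TestSampleOccurrences:
    def test_single_suitable_cell_gets_all_records(self):
        syn = sd.make_env_series(n_slices=1, shape=(8, 8), seed=0)
        sl = syn.series.slices[0]
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 4] = True
        table = sd.sample_occurrences(
            syn.niche, sl, 20, seed=1, variables=syn.variables, region_mask=mask
        )
        lon, lat = sl.grid().cell_center(3, 4)
        assert np.allclose(table.coords(), [[lon, lat]] * 20)

    def test_same_seed_identical_table(self):
        syn = sd.make_env_series(n_slices=1, shape=(10, 10), seed=3)
        sl = syn.series.slices[0]
        t1 = sd.sample_occurrences(syn.niche, sl, 30, seed=4, variables=syn.variables)
        t2 = sd.sample_occurrences(syn.niche, sl, 30, seed=4, variables=syn.variables)
        assert t1.df.equals(t2.df)

    def test_flat_niche_samples_uniformly(self):
        syn = sd.make_env_series(n_slices=1, shape=(6, 6), seed=0)
        sl = syn.series.slices[0]
        flat = sd.TrueNiche(
            linear=np.zeros(3), quadratic=np.zeros(3), intercept=0.0
        )
        table = sd.sample_occurrences(flat, sl, 10_000, seed=5, variables=syn.variables)
        grid = sl.grid()
        counts = np.zeros(36)
        for lon, lat in table.coords():
            i, j = grid.cell_of(lon, lat)
            counts[i * 6 + j] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_zero_suitability_is_error(self):
        syn = sd.make_env_series(n_slices=1, shape=(6, 6), seed=0)
        dead = sd.TrueNiche(
            linear=np.zeros(3), quadratic=np.zeros(3), intercept=-1e9
        )
        with pytest.raises(ValueError, match="zero"):
            sd.sample_occurrences(dead, syn.series.slices[0], 5, seed=0,
                                  variables=syn.variables)


class TestSimulateYuleTree:
    def test_two_tip_root_age_is_exponential(self):
        # with 2 extant lineages the waiting time to the present is
        # Exp(2*lambda): mean 1/(2*lambda)
        lam = 2.0
        ages = [sd.simulate_yule_tree(2, lam, seed=s).root.age for s in range(10_000)]
        assert np.mean(ages) == pytest.approx(1.0 / (2 * lam), rel=0.05)

    def test_output_is_ultrametric_dated_tree(self):
        tree = sd.simulate_yule_tree(12, 0.7, seed=33)
        assert len(tree.tip_ids()) == 12
        assert all(tree.age(t) == 0.0 for t in tree.tip_ids())
        assert tree.root.age > 0

    def test_same_seed_identical_newick(self):
        a = sd.simulate_yule_tree(7, 1.0, seed=5).to_newick()
        b = sd.simulate_yule_tree(7, 1.0, seed=5).to_newick()
        assert a == b

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sd.simulate_yule_tree(1, 1.0, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_yule_tree(5, 0.0, seed=0)


class TestPlantFossils:
    def test_algebraic_inverse_recovers_drawn_r(self):
        tree = sd.simulate_yule_tree(20, 1.0, seed=8)
        points, true_r = sd.plant_fossils(tree, seed=9)
        for p in points:
            r = (tree.age(p.node_id) - p.fad) / p.fad
            assert r == pytest.approx(true_r[p.node_id], abs=1e-12)

    def test_relative_gap_mode_floor(self):
        tree = sd.simulate_yule_tree(10, 1.0, seed=2)
        points, _ = sd.plant_fossils(tree, gap=0.1, seed=3, gap_mode="relative")
        for p in points:
            assert p.fad_min == pytest.approx(0.9 * p.fad)

    def test_oversized_absolute_gap_is_error(self):
        tree = sd.simulate_yule_tree(5, 1.0, seed=4)
        with pytest.raises(ValueError, match="gap"):
            sd.plant_fossils(tree, gap=1e9, seed=5, gap_mode="absolute")


class TestScriptedScenarios:
    def test_ground_truth_masks_are_valid_binary_ranges(self):
        for gen in (sd.scripted_vicariance_series, sd.scripted_founder_series):
            syn = gen(seed=11)
            for m, suit in zip(syn.truth_masks, syn.truth_suitability):
                assert m.dtype == bool
                assert np.array_equal(m, suit >= syn.tau_true)

    def test_vicariance_script_component_count_transition(self):
        syn = sd.scripted_vicariance_series(seed=4)
        counts = [label_components(m).n_components for m in syn.truth_masks]
        assert all(c == 1 for c in counts[: syn.event_index])
        assert all(c == 2 for c in counts[syn.event_index:])

    def test_founder_script_merges_exactly_during_pulse(self):
        syn = sd.scripted_founder_series(seed=4)
        counts = [label_components(m).n_components for m in syn.truth_masks]
        for k, c in enumerate(counts):
            assert c == (1 if k == syn.event_index else 2)


class TestDemoWorkspace:
    def test_workspace_is_complete_and_loadable(self, tmp_path):
        from paleorange.io_formats import (
            read_env_series, read_newick, read_occurrences,
        )
        from paleorange.calibration import read_calibration_table

        man = sd.make_demo_workspace(tmp_path / "ws", seed=1)
        tree = read_newick(tmp_path / "ws" / "tree.nwk")
        occ = read_occurrences(tmp_path / "ws" / "occurrences.csv")
        series = read_env_series(tmp_path / "ws" / "slices")
        points = read_calibration_table(tmp_path / "ws" / "calibration.csv")
        assert sorted(tree.tip_ids()) == man["tree_tips"]
        assert occ.unmatched_species(tree) == []
        assert series.ages == man["slice_ages"]
        assert len(points) == man["n_calibrations"]
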