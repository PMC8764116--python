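"""Component labeling, occupancy propagation, event grammar, verdicts."""

import numpy as np
import pytest

from paleorange import fragmentation as frag
from paleorange.synthetic_data import (
    scripted_founder_series,
    scripted_vicariance_series,
)
from conftest import brute_force_occupancy, flood_fill_components


class TestLabelComponents:
    def test_adjacency_semantics_on_diagonal_blobs(self):
        m = np.array([[1, 0], [0, 1]], dtype=bool)
        assert frag.label_components(m, "rook").n_components == 2
        assert frag.label_components(m, "queen").n_components == 1

    def test_empty_map(self):
        lab = frag.label_components(np.zeros((4, 4), dtype=bool))
        assert lab.n_components == 0 and lab.sizes() == {}

    @pytest.mark.parametrize("adjacency", ["rook", "queen"])
    def test_random_maps_match_flood_fill_oracle(self, adjacency):
        rng = np.random.default_rng(101)
        for _ in range(25):
            m = rng.uniform(size=(20, 20)) < 0.45
            lab = frag.label_components(m, adjacency)
            ref = flood_fill_components(m, adjacency)
            assert np.array_equal(lab.labels, ref)

    def test_scanline_label_order(self):
        m = np.zeros((3, 5), dtype=bool)
        m[2, 0] = True   # encountered later in raster order
        m[0, 4] = True   # encountered first
        lab = frag.label_components(m)
        assert lab.labels[0, 4] == 1 and lab.labels[2, 0] == 2


class TestSeedOccupancy:
    def test_only_evidenced_component_occupied(self):
        m = np.zeros((4, 4), dtype=bool)
        m[0, :2] = True
        m[3, 2:] = True
        lab = frag.label_components(m)
        assert frag.seed_occupancy(lab, [(0, 0)]) == {1}
        assert frag.seed_occupancy(lab, [(0, 0), (3, 3)]) == {1, 2}

    def test_no_evidence_seeds_largest_with_warning(self):
        m = np.zeros((4, 4), dtype=bool)
        m[0, :3] = True
        m[3, 3] = True
        lab = frag.label_components(m)
        with pytest.warns(RuntimeWarning, match="largest"):
            occ = frag.seed_occupancy(lab, [(2, 0)])
        assert occ == {1}

    def test_empty_labeling_is_error(self):
        lab = frag.label_components(np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError, match="no range components"):
            frag.seed_occupancy(lab, [(0, 0)])


class TestPropagateOccupancy:
    def test_identical_maps_preserve_occupancy(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:3, 1:3] = True
        lab = frag.label_components(m)
        assert frag.propagate_occupancy(lab, {1}, lab, 0) == {1}

    def test_distant_isolate_stays_empty(self):
        a = np.zeros((5, 15), dtype=bool)
        a[2, 0] = True
        b = a.copy()
        b[2, 11] = True
        lab_a, lab_b = frag.label_components(a), frag.label_components(b)
        occ = frag.propagate_occupancy(lab_a, {1}, lab_b, dispersal_radius=1)
        assert occ == {1}  # the far cell is component 2, 10 cells away

    @pytest.mark.parametrize("radius", [0, 1, 3])
    def test_random_pairs_match_brute_force_chebyshev(self, radius):
        rng = np.random.default_rng(300 + radius)
        for _ in range(12):
            a = rng.uniform(size=(18, 18)) < 0.25
            b = rng.uniform(size=(18, 18)) < 0.25
            lab_a, lab_b = frag.label_components(a), frag.label_components(b)
            if lab_a.n_components == 0:
                continue
            occupied = set(
                rng.choice(lab_a.component_ids,
                           size=max(1, lab_a.n_components // 2), replace=False)
                .tolist()
            )
            got = frag.propagate_occupancy(lab_a, occupied, lab_b, radius)
            ref = brute_force_occupancy(lab_a.labels, occupied, lab_b.labels, radius)
            assert got == ref


def _series_from_masks(masks, seed_cells, radius=1):
    ages = [0.01 * (len(masks) - 1 - k) for k in range(len(masks))]
    return frag.build_occupancy(masks, ages, seed_cells, radius, "rook")


class TestDetectEvents:
    def test_constructed_split(self):
        whole = np.zeros((6, 10), dtype=bool)
        whole[2:4, 1:9] = True
        halves = whole.copy()
        halves[:, 4:6] = False
        occ = _series_from_masks([whole, halves], [(2, 2)])
        events = frag.detect_events(occ)
        kinds = [e.kind for e in events]
        assert kinds == ["SPLIT"]
        assert events[0].components["children"] == [1, 2]

    def test_constant_range_has_no_events(self):
        m = np.zeros((6, 6), dtype=bool)
        m[2:4, 2:4] = True
        occ = _series_from_masks([m] * 5, [(2, 2)])
        assert frag.detect_events(occ) == []

    def test_scripted_corridor_pulse_opens_then_closes(self):
        blobs = np.zeros((6, 14), dtype=bool)
        blobs[2:4, 0:4] = True
        blobs[2:4, 10:14] = True
        joined = blobs.copy()
        joined[2:4, 4:10] = True
        occ = _series_from_masks([blobs, joined, blobs, blobs], [(2, 1)])
        events = frag.detect_events(occ)
        kinds = [e.kind for e in events]
        assert "CORRIDOR_OPEN" in kinds and "CORRIDOR_CLOSE" in kinds
        assert "SPLIT" not in kinds  # the closure is not a vicariant split
        close = next(e for e in events if e.kind == "CORRIDOR_CLOSE")
        assert close.detail["founder_persists"]
        # far blob occupied from the pulse onward
        assert occ.slices[2].occupied == {1, 2}

    def test_extinction_of_unreachable_component(self):
        both = np.zeros((6, 14), dtype=bool)
        both[2:4, 0:3] = True
        both[2:4, 11:14] = True
        left = both.copy()
        left[:, 11:] = False
        occ = _series_from_masks([both, left], [(2, 1), (2, 12)])
        kinds = [e.kind for e in frag.detect_events(occ)]
        assert kinds == ["EXTINCTION"]

    def test_single_slice_rejected(self):
        m = np.ones((3, 3), dtype=bool)
        occ = _series_from_masks([m], [(0, 0)])
        with pytest.raises(ValueError, match="at least 2"):
            frag.detect_events(occ)

    def test_event_lists_deterministic(self):
        syn = scripted_founder_series(seed=6)
        cells = [tuple(c) for c in np.argwhere(syn.occurrence_mask)]
        outs = []
        for _ in range(2):
            occ = frag.build_occupancy(
                syn.truth_masks, syn.series.ages, cells, 1, "rook"
            )
            outs.append(repr(frag.detect_events(occ)))
        assert outs[0] == outs[1]


class TestClassifyScenario:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_scripted_founder_series(self, seed):
        syn = scripted_founder_series(seed=seed)
        cells = [tuple(c) for c in np.argwhere(syn.occurrence_mask)]
        occ = frag.build_occupancy(syn.truth_masks, syn.series.ages, cells, 1, "rook")
        sc = frag.classify_scenario("n", frag.detect_events(occ))
        assert sc.verdict == "founder"
        assert abs(sc.event_age_hi - syn.event_age) <= 0.011

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_scripted_vicariance_series(self, seed):
        syn = scripted_vicariance_series(seed=seed)
        cells = [tuple(c) for c in np.argwhere(syn.occurrence_mask)]
        occ = frag.build_occupancy(syn.truth_masks, syn.series.ages, cells, 1, "rook")
        sc = frag.classify_scenario("n", frag.detect_events(occ))
        assert sc.verdict == "vicariance"
        assert abs(sc.event_age_lo - syn.event_age) <= 0.011

    def test_no_events_gives_none(self):
        sc = frag.classify_scenario("n", [])
        assert sc.verdict == "none" and sc.event_age_lo is None

    def test_occupied_never_exceeds_suitable(self):
        syn = scripted_founder_series(seed=9)
        cells = [tuple(c) for c in np.argwhere(syn.occurrence_mask)]
        occ = frag.build_occupancy(syn.truth_masks, syn.series.ages, cells, 1, "rook")
        for sl, suitable in zip(occ.slices, syn.truth_masks):
            assert sl.occupied_mask().sum() <= suitable.sum()
            assert np.all(suitable[sl.occupied_mask()])
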