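"""Range fragmentation through time: components, occupancy, speciation events.

Binarized suitability maps per time slice are labeled into connected
components (rook or queen adjacency).  Occupancy — whether a suitable
component actually holds the lineage — is seeded at the oldest slice from
pooled occurrence evidence and propagated forward: a component is occupied
iff any of its cells is within the dispersal radius (Chebyshev distance,
in cells) of an occupied cell of the previous slice.

Transitions between slices are parsed into an event grammar: SPLIT, MERGE,
CORRIDOR_OPEN (a previously unoccupied suitable component becomes
reachable), CORRIDOR_CLOSE (a tracked corridor connection disappears with
both sides occupied) and EXTINCTION.  A divergence is then classified as

* vicariance — an occupied range SPLITs and both isolates stay occupied
  through the end of the analysis window;
* founder event — a CORRIDOR_OPEN followed by CORRIDOR_CLOSE leaving a
  newly colonized isolate that persists, occupied and disconnected;
* ambiguous — both patterns present; none — neither.

The grammar is a deterministic formalization of range-map inspection; the
fragmentation of a component that was itself assembled by a tracked
corridor opening is reported as the corridor closing, not as a split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ComponentLabeling",
    "SliceOccupancy",
    "OccupancySeries",
    "RangeEvent",
    "SpeciationScenario",
    "label_components",
    "seed_occupancy",
    "propagate_occupancy",
    "build_occupancy",
    "detect_events",
    "classify_scenario",
]

_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_QUEEN = np.ones((3, 3), dtype=bool)


def _structure(adjacency: str) -> np.ndarray:
    if adjacency == "rook":
        return _ROOK
    if adjacency == "queen":
        return _QUEEN
    raise ValueError(f"unknown adjacency {adjacency!r}; use 'rook' or 'queen'")


@dataclass
class ComponentLabeling:
    """Integer labels per cell (0 = out of range), scanline-ordered."""

    labels: np.ndarray
    adjacency: str

    @property
    def n_components(self) -> int:
        return int(self.labels.max())

    @property
    def component_ids(self) -> list[int]:
        return list(range(1, self.n_components + 1))

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def mask_of(self, comp_id: int) -> np.ndarray:
        return self.labels == comp_id

    def centroid(self, comp_id: int) -> tuple[float, float]:
        ii, jj = np.nonzero(self.labels == comp_id)
        return float(ii.mean()), float(jj.mean())


def label_components(range_map: np.ndarray, adjacency: str = "rook") -> ComponentLabeling:
    """Maximal connected components, labels in first-encounter scanline order."""
    mask = np.asarray(range_map).astype(bool)
    raw, n = ndimage.label(mask, structure=_structure(adjacency))
    if n > 0:
        flat = raw.ravel()
        nz = flat > 0
        # first flat index at which each raw label appears
        first = np.full(n + 1, flat.size, dtype=np.int64)
        idx = np.flatnonzero(nz)
        np.minimum.at(first, flat[idx], idx)
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=np.int64)
        remap[1 + order] = np.arange(1, n + 1)
        raw = remap[raw]
    return ComponentLabeling(raw, adjacency)


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Chebyshev-ball dilation: all cells within `radius` of the mask."""
    if radius <= 0 or not mask.any():
        return mask
    return ndimage.binary_dilation(mask, structure=_QUEEN, iterations=radius)


def seed_occupancy(
    labeling: ComponentLabeling, occurrence_cells: Iterable[tuple[int, int]]
) -> set[int]:
    """Occupied components at the oldest slice, from occurrence evidence.

    A component is occupied iff it contains at least one occurrence cell;
    if no component does, the largest one is seeded with a warning.
    """
    if labeling.n_components == 0:
        raise ValueError("cannot seed occupancy: no range components in first slice")
    occupied = set()
    for (i, j) in occurrence_cells:
        lab = int(labeling.labels[i, j])
        if lab > 0:
            occupied.add(lab)
    if not occupied:
        sizes = labeling.sizes()
        largest = max(sizes, key=lambda k: (sizes[k], -k))
        warnings.warn(
            "no occurrence falls inside the oldest-slice range; seeding the "
            f"largest component ({largest}, {sizes[largest]} cells)",
            RuntimeWarning,
        )
        occupied = {largest}
    return occupied


def propagate_occupancy(
    prev: ComponentLabeling,
    prev_occupied: set[int],
    nxt: ComponentLabeling,
    dispersal_radius: int = 1,
) -> set[int]:
    """Occupied components of the next slice.

    A next-slice component is occupied iff any of its cells lies within
    ``dispersal_radius`` (Chebyshev) of an occupied previous-slice cell.
    """
    if prev.labels.shape != nxt.labels.shape:
        raise ValueError("labelings are not co-registered")
    if not prev_occupied:
        return set()
    occ_mask = np.isin(prev.labels, list(prev_occupied))
    reach = _dilate(occ_mask, dispersal_radius)
    return {int(v) for v in np.unique(nxt.labels[reach]) if v > 0}


@dataclass
class SliceOccupancy:
    age: float
    labeling: ComponentLabeling
    occupied: set[int]

    def occupied_mask(self) -> np.ndarray:
        if not self.occupied:
            return np.zeros_like(self.labeling.labels, dtype=bool)
        return np.isin(self.labeling.labels, list(self.occupied))


@dataclass
class OccupancySeries:
    """Per-slice labelings with occupancy flags, old -> young."""

    slices: list[SliceOccupancy]
    dispersal_radius: int
    adjacency: str

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def ages(self) -> list[float]:
        return [s.age for s in self.slices]


def build_occupancy(
    range_maps: Sequence[np.ndarray],
    ages: Sequence[float],
    occurrence_cells: Iterable[tuple[int, int]],
    dispersal_radius: int = 1,
    adjacency: str = "rook",
) -> OccupancySeries:
    """Label every slice, seed the oldest from evidence, propagate forward."""
    if len(range_maps) != len(ages):
        raise ValueError("one age per range map required")
    labelings = [label_components(m, adjacency) for m in range_maps]
    occ = [seed_occupancy(labelings[0], occurrence_cells)]
    for k in range(1, len(labelings)):
        occ.append(
            propagate_occupancy(labelings[k - 1], occ[-1], labelings[k], dispersal_radius)
        )
    slices = [
        SliceOccupancy(age, lab, flags)
        for age, lab, flags in zip(ages, labelings, occ)
    ]
    return OccupancySeries(slices, dispersal_radius, adjacency)


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

@dataclass
class RangeEvent:
    kind: str          # SPLIT | MERGE | CORRIDOR_OPEN | CORRIDOR_CLOSE | EXTINCTION
    age: float         # age of the slice where the new state is first seen
    index: int         # slice index of that state
    components: dict = field(default_factory=dict)
    detail: dict = field(default_factory=dict)


@dataclass
class _Corridor:
    open_index: int
    open_age: float
    source_mask: np.ndarray   # occupied side at opening
    target_mask: np.ndarray   # previously unoccupied suitable side
    closed: bool = False


def _reach_map(prev: SliceOccupancy, nxt: SliceOccupancy, radius: int):
    """Bipartite reachability between components of consecutive slices."""
    p2n: dict[int, set[int]] = {}
    n2p: dict[int, set[int]] = {c: set() for c in nxt.labeling.component_ids}
    for c in prev.labeling.component_ids:
        reach = _dilate(prev.labeling.mask_of(c), radius)
        nxts = {int(v) for v in np.unique(nxt.labeling.labels[reach]) if v > 0}
        p2n[c] = nxts
        for d in nxts:
            n2p[d].add(c)
    return p2n, n2p


def _comps_reached(mask: np.ndarray, sl: SliceOccupancy, radius: int) -> set[int]:
    reach = _dilate(mask, radius)
    return {int(v) for v in np.unique(sl.labeling.labels[reach]) if v > 0}


def _union_mask(sl: SliceOccupancy, comps: set[int]) -> np.ndarray:
    if not comps:
        return np.zeros_like(sl.labeling.labels, dtype=bool)
    return np.isin(sl.labeling.labels, list(comps))


def _connected(mask_a: np.ndarray, mask_b: np.ndarray, radius: int) -> bool:
    return bool((_dilate(mask_a, radius) & mask_b).any())


def _persists_occupied(
    series: OccupancySeries, start_index: int, mask: np.ndarray
) -> bool:
    """True iff the masked range keeps an occupied successor to the last slice."""
    r = series.dispersal_radius
    cur = mask
    for k in range(start_index + 1, len(series)):
        nxt = series.slices[k]
        comps = _comps_reached(cur, nxt, r) & nxt.occupied
        if not comps:
            return False
        cur = _union_mask(nxt, comps)
    return True


def _stays_isolated(
    series: OccupancySeries, start_index: int,
    target_mask: np.ndarray, source_mask: np.ndarray,
) -> bool:
    """Founder persistence: target stays occupied and never reconnects."""
    r = series.dispersal_radius
    tgt, src = target_mask, source_mask
    for k in range(start_index + 1, len(series)):
        nxt = series.slices[k]
        t_comps = _comps_reached(tgt, nxt, r) & nxt.occupied
        if not t_comps:
            return False
        s_comps = _comps_reached(src, nxt, r) & nxt.occupied
        t_mask = _union_mask(nxt, t_comps)
        s_mask = _union_mask(nxt, s_comps)
        if t_comps & s_comps or _connected(t_mask, s_mask, r):
            return False
        tgt, src = t_mask, s_mask
        if not s_comps:
            # the source side went extinct; the isolate only needs to persist
            src = np.zeros_like(t_mask)
    return True


def detect_events(series: OccupancySeries) -> list[RangeEvent]:
    """Parse slice-to-slice transitions into range events.

    Slices must be ordered old -> young; at least 2 are required.  Event
    ages are the age of the younger slice of each transition.  SPLIT and
    CORRIDOR_CLOSE events carry persistence annotations used by
    :func:`classify_scenario`.
    """
    if len(series) < 2:
        raise ValueError("event detection needs at least 2 slices")
    radius = series.dispersal_radius
    events: list[RangeEvent] = []
    corridors: list[_Corridor] = []

    for t in range(len(series) - 1):
        prev, nxt = series.slices[t], series.slices[t + 1]
        p2n, n2p = _reach_map(prev, nxt, radius)

        # -- corridor closure / continuation ---------------------------
        suppressed_splits: set[int] = set()
        for rec in corridors:
            if rec.closed:
                continue
            t_comps = _comps_reached(rec.target_mask, nxt, radius) & nxt.occupied
            s_comps = _comps_reached(rec.source_mask, nxt, radius) & nxt.occupied
            if not t_comps:
                rec.closed = True  # colonist extinct; corridor record dead
                continue
            t_mask = _union_mask(nxt, t_comps)
            s_mask = _union_mask(nxt, s_comps)
            still_joined = bool(t_comps & s_comps) or _connected(t_mask, s_mask, radius)
            if still_joined:
                rec.target_mask = t_mask
                rec.source_mask = s_mask if s_comps else rec.source_mask
                continue
            # the connection disappeared with both sides occupied
            rec.closed = True
            persists = _stays_isolated(series, t + 1, t_mask, s_mask)
            events.append(
                RangeEvent(
                    kind="CORRIDOR_CLOSE",
                    age=nxt.age,
                    index=t + 1,
                    components={"target": sorted(t_comps), "source": sorted(s_comps)},
                    detail={
                        "open_age": rec.open_age,
                        "open_index": rec.open_index,
                        "founder_persists": persists,
                        "isolate_size": int(t_mask.sum()),
                        "isolate_centroid": tuple(
                            float(v) for v in np.argwhere(t_mask).mean(axis=0)
                        ),
                    },
                )
            )
            # the fragmentation realizing this closure is not a vicariant split
            for c in prev.occupied:
                reached = p2n.get(c, set())
                if reached & t_comps and reached & s_comps:
                    suppressed_splits.add(c)

        # -- corridor openings and merges ------------------------------
        for d in sorted(nxt.occupied):
            prevs = n2p.get(d, set())
            occ_prevs = {c for c in prevs if c in prev.occupied}
            unocc_prevs = prevs - occ_prevs
            if occ_prevs and unocc_prevs:
                src = _union_mask(prev, occ_prevs)
                tgt = _union_mask(prev, unocc_prevs)
                events.append(
                    RangeEvent(
                        kind="CORRIDOR_OPEN",
                        age=nxt.age,
                        index=t + 1,
                        components={
                            "merged": d,
                            "source": sorted(occ_prevs),
                            "newly_reachable": sorted(unocc_prevs),
                        },
                        detail={"target_size": int(tgt.sum())},
                    )
                )
                corridors.append(_Corridor(t + 1, nxt.age, src, tgt))
            if len(occ_prevs) >= 2:
                events.append(
                    RangeEvent(
                        kind="MERGE",
                        age=nxt.age,
                        index=t + 1,
                        components={"merged": d, "sources": sorted(occ_prevs)},
                    )
                )

        # -- splits and extinctions ------------------------------------
        for c in sorted(prev.occupied):
            occ_nxts = p2n.get(c, set()) & nxt.occupied
            if not occ_nxts:
                events.append(
                    RangeEvent(
                        kind="EXTINCTION",
                        age=nxt.age,
                        index=t + 1,
                        components={"component": c},
                    )
                )
            elif len(occ_nxts) >= 2 and c not in suppressed_splits:
                persisting = []
                for d in sorted(occ_nxts):
                    m = nxt.labeling.mask_of(d)
                    persisting.append(_persists_occupied(series, t + 1, m))
                sizes = nxt.labeling.sizes()
                events.append(
                    RangeEvent(
                        kind="SPLIT",
                        age=nxt.age,
                        index=t + 1,
                        components={"parent": c, "children": sorted(occ_nxts)},
                        detail={
                            "both_persist": sum(persisting) >= 2,
                            "child_sizes": [sizes[d] for d in sorted(occ_nxts)],
                            "child_centroids": [
                                nxt.labeling.centroid(d) for d in sorted(occ_nxts)
                            ],
                        },
                    )
                )
    return events


# ---------------------------------------------------------------------------
# Scenario classification
# ---------------------------------------------------------------------------

@dataclass
class SpeciationScenario:
    node_id: str
    verdict: str                       # vicariance | founder | ambiguous | none
    event_age_lo: float | None = None
    event_age_hi: float | None = None
    events: list[RangeEvent] = field(default_factory=list)
    note: str = ""


def classify_scenario(
    node_id: str, events: Sequence[RangeEvent]
) -> SpeciationScenario:
    """Vicariance vs founder-event verdict from a window's event list.

    Vicariance requires a SPLIT whose isolates stay occupied through the
    window; founder requires a CORRIDOR_OPEN followed by CORRIDOR_CLOSE
    with the newly colonized isolate persisting.  Both patterns present
    gives ``ambiguous`` (no forced tie-break); neither gives ``none``.
    """
    vic = [e for e in events if e.kind == "SPLIT" and e.detail.get("both_persist")]
    fou = [
        e
        for e in events
        if e.kind == "CORRIDOR_CLOSE" and e.detail.get("founder_persists")
    ]
    support: list[RangeEvent] = []
    if vic and fou:
        verdict = "ambiguous"
        support = vic + fou
    elif vic:
        verdict = "vicariance"
        support = vic
    elif fou:
        verdict = "founder"
        support = fou
    else:
        verdict = "none"
    ages: list[float] = []
    for e in support:
        ages.append(e.age)
        if e.kind == "CORRIDOR_CLOSE":
            ages.append(e.detail["open_age"])
    return SpeciationScenario(
        node_id=node_id,
        verdict=verdict,
        event_age_lo=min(ages) if ages else None,
        event_age_hi=max(ages) if ages else None,
        events=list(events),
    )
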