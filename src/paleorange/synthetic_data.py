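"""Synthetic inputs with exposed ground truth.

Everything the pipeline consumes can be generated here: smooth
multi-variable environmental fields drifting over time slices, scripted
barrier-formation and transient-corridor events, occurrence records
sampled from a known logistic niche, Yule trees, and fossil first
appearance data planted from a known relative ghost-time distribution.
Every generator is a pure function of its parameters and seed, and each
returns the ground truth needed to test the downstream modules against
what was actually generated.

The landscapes are sums of Gaussian bumps on a small lat/lon grid — a
deliberately stylized stand-in for bioclimatic layers that has the one
property the pipeline cares about: controllable connectivity of the
suitable area through time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .calibration import CalibrationPoint
from .io_formats import (
    DatedTree,
    EnvSlice,
    EnvSliceSeries,
    OccurrenceTable,
    RasterGrid,
)

__all__ = [
    "TrueNiche",
    "ScriptedEvent",
    "SyntheticSeries",
    "make_env_series",
    "scripted_vicariance_series",
    "scripted_founder_series",
    "sample_occurrences",
    "simulate_yule_tree",
    "plant_fossils",
    "scale_tree",
    "make_demo_workspace",
    "logistic_niche_fixture",
]

_DEFAULT_SHAPE = (40, 40)
_DEFAULT_N_SLICES = 10
_DEFAULT_N_VARIABLES = 3


@dataclass
class TrueNiche:
    """Known logistic niche: suitability = sigmoid(b0 + w.x + u.x^2)."""

    linear: np.ndarray
    quadratic: np.ndarray
    intercept: float

    def suitability(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return expit(self.intercept + X @ self.linear + (X**2) @ self.quadratic)

    def suitability_grid(self, env_slice: EnvSlice, variables: Sequence[str]) -> np.ndarray:
        stack = np.stack(
            [env_slice.variables[v].values for v in variables], axis=-1
        )
        flat = stack.reshape(-1, len(variables))
        return self.suitability(flat).reshape(stack.shape[:2])


@dataclass
class ScriptedEvent:
    """A scripted modification of the driver field.

    ``barrier``: a band of cells pushed below niche tolerance from
    ``start`` slice onward; ``corridor_pulse``: a band made suitable only
    during [start, end].  Bands are axis-aligned: rows ``rows[0]:rows[1]``
    by cols ``cols[0]:cols[1]`` (half-open, grid indices).
    """

    kind: str
    start: int
    end: int
    rows: tuple[int, int]
    cols: tuple[int, int]

    def __post_init__(self):
        if self.kind not in ("barrier", "corridor_pulse"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError("event start must be <= end")

    def band(self, shape: tuple[int, int]) -> np.ndarray:
        if not (0 <= self.rows[0] < self.rows[1] <= shape[0]
                and 0 <= self.cols[0] < self.cols[1] <= shape[1]):
            raise ValueError(f"event band {self.rows}x{self.cols} outside grid {shape}")
        m = np.zeros(shape, dtype=bool)
        m[self.rows[0]:self.rows[1], self.cols[0]:self.cols[1]] = True
        return m

    def active(self, slice_index: int) -> bool:
        if self.kind == "barrier":
            return slice_index >= self.start
        return self.start <= slice_index <= self.end


@dataclass
class SyntheticSeries:
    """A generated slice series with its ground truth."""

    series: EnvSliceSeries
    niche: TrueNiche
    variables: list[str]
    tau_true: float
    truth_suitability: list[np.ndarray]   # old -> young
    truth_masks: list[np.ndarray]
    events: list[ScriptedEvent]
    scripted_kind: str | None = None
    event_index: int | None = None
    event_age: float | None = None
    occurrence_mask: np.ndarray | None = None


def _gaussian_bump(shape, center, sigma, amplitude=1.0):
    ii, jj = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2
    return amplitude * np.exp(-d2 / (2.0 * sigma**2))


def make_env_series(
    n_slices: int = _DEFAULT_N_SLICES,
    shape: tuple[int, int] = _DEFAULT_SHAPE,
    n_variables: int = _DEFAULT_N_VARIABLES,
    bumps: Sequence[tuple[tuple[float, float], float, float]] | None = None,
    events: Sequence[ScriptedEvent] = (),
    drift: float = 0.05,
    seed: int = 0,
    age_step: float = 0.01,
    oldest_age: float | None = None,
    cellsize: float = 0.5,
    xll: float = 40.0,
    yll: float = 20.0,
    tau_true: float = 0.5,
    steepness: float = 12.0,
) -> SyntheticSeries:
    """Environmental slice series with scripted connectivity events.

    The first variable ``env1`` is the niche driver: a max-of-Gaussian-bumps
    field in [0, 1]; the true niche is sigmoid(steepness * (env1 - 0.5)) so
    the ground-truth range at ``tau_true = 0.5`` is exactly ``env1 > 0.5``.
    Barriers zero the driver in their band from their start slice onward;
    corridor pulses raise it to 1 while active.  Remaining variables are
    smooth nuisance fields with gentle temporal drift.
    """
    rng = np.random.default_rng(seed)
    if bumps is None:
        bumps = [((shape[0] / 2, shape[1] / 2), min(shape) / 4.5, 1.0)]
    # contradictory overlap: a barrier and a corridor active together on
    # shared cells would demand the driver be both 0 and 1
    for a in events:
        for b in events:
            if a is b or a.kind == b.kind:
                continue
            if (a.band(shape) & b.band(shape)).any() and not (
                a.end < b.start or b.end < a.start
            ):
                raise ValueError(
                    "contradictory scripted events: barrier and corridor overlap "
                    "in both cells and time"
                )
    base = np.zeros(shape)
    for center, sigma, amp in bumps:
        base = np.maximum(base, _gaussian_bump(shape, center, sigma, amp))
    nuisance = [
        sum(
            _gaussian_bump(
                shape,
                (rng.uniform(0, shape[0]), rng.uniform(0, shape[1])),
                rng.uniform(4, 10),
                rng.uniform(0.5, 1.5),
            )
            for _ in range(4)
        )
        for _ in range(n_variables - 1)
    ]
    drift_dir = [rng.normal(size=shape) * 0 + rng.normal() for _ in nuisance]

    if oldest_age is None:
        oldest_age = age_step * (n_slices - 1)
    if n_slices == 1:
        ages = [0.0]
    else:
        ages = [
            round(oldest_age - k * (oldest_age / (n_slices - 1)), 9)
            for k in range(n_slices)
        ]

    niche = TrueNiche(
        linear=np.array([steepness] + [0.0] * (n_variables - 1)),
        quadratic=np.zeros(n_variables),
        intercept=-steepness * tau_true,
    )

    slices, truth_suit, truth_masks = [], [], []
    for k, age in enumerate(ages):
        driver = base.copy()
        for ev in events:
            if ev.active(k):
                band = ev.band(shape)
                if ev.kind == "barrier":
                    driver[band] = 0.0
                else:
                    driver[band] = 1.0
        variables = {"env1": RasterGrid(driver, xll, yll, cellsize)}
        for m, nf in enumerate(nuisance):
            field_k = nf + drift * k * drift_dir[m]
            variables[f"env{m + 2}"] = RasterGrid(field_k, xll, yll, cellsize)
        slices.append(EnvSlice(age, variables))
        suit = expit(niche.intercept + niche.linear[0] * driver)
        truth_suit.append(suit)
        truth_masks.append(suit >= tau_true)

    names = sorted(slices[0].variables)
    return SyntheticSeries(
        series=EnvSliceSeries(slices),
        niche=niche,
        variables=names,
        tau_true=tau_true,
        truth_suitability=truth_suit,
        truth_masks=truth_masks,
        events=list(events),
    )


def scripted_vicariance_series(
    seed: int,
    n_slices: int = 8,
    shape: tuple[int, int] = _DEFAULT_SHAPE,
    age_step: float = 0.01,
) -> SyntheticSeries:
    """One broad occupied range cut in two by a barrier at a random slice.

    The barrier band (3 cells wide, beyond the default dispersal radius)
    appears at a seeded slice index in [2, n_slices - 2] and persists, so
    both halves remain occupied: the classical vicariance pattern.
    """
    rng = np.random.default_rng(seed)
    event_index = int(rng.integers(2, n_slices - 1))
    cut = int(rng.integers(shape[1] // 2 - 4, shape[1] // 2 + 4))
    jitter = (float(rng.uniform(-1.5, 1.5)), float(rng.uniform(-1.5, 1.5)))
    center = (shape[0] / 2 + jitter[0], shape[1] / 2 + jitter[1])
    ev = ScriptedEvent(
        "barrier", event_index, n_slices - 1, rows=(0, shape[0]), cols=(cut - 1, cut + 2)
    )
    out = make_env_series(
        n_slices=n_slices,
        shape=shape,
        bumps=[(center, min(shape) / 3.2, 1.0)],
        events=[ev],
        seed=seed,
        age_step=age_step,
    )
    out.scripted_kind = "vicariance"
    out.event_index = event_index
    out.event_age = out.series.ages[event_index]
    out.occurrence_mask = out.truth_masks[0]
    return out


def scripted_founder_series(
    seed: int,
    n_slices: int = 8,
    shape: tuple[int, int] = _DEFAULT_SHAPE,
    age_step: float = 0.01,
) -> SyntheticSeries:
    """Two suitable blobs, only one occupied; a one-slice corridor pulse.

    The corridor connects the occupied blob to the suitable-but-empty one
    at a seeded slice index, closes the next slice, and the colonized
    isolate persists: the founder-event pattern.
    """
    rng = np.random.default_rng(seed)
    event_index = int(rng.integers(2, n_slices - 2))
    row_c = shape[0] / 2 + float(rng.uniform(-2, 2))
    c_a = (row_c, shape[1] * 0.22 + float(rng.uniform(-1, 1)))
    c_b = (row_c, shape[1] * 0.78 + float(rng.uniform(-1, 1)))
    sigma = min(shape) / 7.5
    r0 = int(round(row_c)) - 1
    ev = ScriptedEvent(
        "corridor_pulse",
        event_index,
        event_index,
        rows=(max(r0, 0), min(r0 + 3, shape[0])),
        cols=(int(c_a[1]), int(c_b[1]) + 1),
    )
    out = make_env_series(
        n_slices=n_slices,
        shape=shape,
        bumps=[(c_a, sigma, 1.0), (c_b, sigma, 1.0)],
        events=[ev],
        seed=seed,
        age_step=age_step,
    )
    out.scripted_kind = "founder"
    out.event_index = event_index
    out.event_age = out.series.ages[event_index]
    # occupied side only: the western blob at the oldest slice
    half = np.zeros(shape, dtype=bool)
    half[:, : shape[1] // 2] = True
    out.occurrence_mask = out.truth_masks[0] & half
    return out


def sample_occurrences(
    niche: TrueNiche,
    env_slice: EnvSlice,
    n: int,
    seed: int,
    variables: Sequence[str] | None = None,
    species: str = "sp1",
    region_mask: np.ndarray | None = None,
) -> OccurrenceTable:
    """Records at cell centers, cells drawn proportional to true suitability."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    variables = list(variables or sorted(env_slice.variables))
    suit = niche.suitability_grid(env_slice, variables)
    valid = env_slice.valid_mask()
    w = np.where(valid, suit, 0.0)
    if region_mask is not None:
        w = np.where(region_mask, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample occurrences")
    flat = w.ravel() / total
    cells = rng.choice(len(flat), size=n, p=flat)
    grid = env_slice.grid()
    ii, jj = np.unravel_index(cells, w.shape)
    lons, lats = zip(*(grid.cell_center(i, j) for i, j in zip(ii, jj)))
    return OccurrenceTable(
        pd.DataFrame({"species": species, "lon": lons, "lat": lats})
    )


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> DatedTree:
    """Pure-birth (Yule) tree with tips at the present; ages in My.

    Forward simulation: after the root split, each of k extant lineages
    splits at total rate k*lambda; the clock stops one exponential waiting
    time after the n-th tip arises, so a 2-tip tree has root age
    distributed Exp(2*lambda).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)

    def stub(start):
        return {"start": start, "children": None}

    root = {"start": 0.0, "time": 0.0, "children": [stub(0.0), stub(0.0)]}
    t = 0.0
    active = list(root["children"])
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        node["time"] = t
        node["children"] = [stub(t), stub(t)]
        active.extend(node["children"])
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))

    labels = iter(f"sp{i + 1}" for i in range(n_tips))

    def newick(node) -> str:
        if node["children"] is None:
            name = next(labels)
            return f"{name}:{t_end - node['start']:.12g}"
        inner = ",".join(newick(c) for c in node["children"])
        ln = node["time"] - node["start"]
        return f"({inner}):{ln:.12g}"

    text = newick(root).rsplit(":", 1)[0] + ";"
    return DatedTree.from_newick_string(text)


def plant_fossils(
    tree: DatedTree,
    meanlog: float = -1.0,
    sdlog: float = 0.3,
    gap: float = 0.1,
    seed: int = 0,
    node_ids: Sequence[str] | None = None,
    gap_mode: str = "relative",
) -> tuple[list[CalibrationPoint], dict[str, float]]:
    """Fossil FADs from a known relative ghost-time distribution.

    For each selected internal node with age Td, draw r ~ Lognormal and
    set FAD = Td / (1 + r).  The stratigraphic-zone floor is
    FAD_min = FAD - gap (``gap_mode='absolute'``, My) or
    FAD_min = FAD * (1 - gap) (``gap_mode='relative'``, default, so the
    gap can never swallow the FAD on shallow nodes).  Returns the
    calibration points and the true r per node for recovery tests.
    """
    rng = np.random.default_rng(seed)
    if node_ids is None:
        node_ids = sorted(tree.internal_ids(), key=lambda n: -tree.age(n))
    if gap_mode not in ("absolute", "relative"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    points, true_r = [], {}
    for nid in node_ids:
        td = tree.age(nid)
        if td <= 0:
            raise ValueError(f"node {nid} has non-positive age")
        r = float(rng.lognormal(meanlog, sdlog))
        fad = td / (1.0 + r)
        g = gap * fad if gap_mode == "relative" else gap
        if g >= fad:
            raise ValueError(
                f"stratigraphic gap {g:.6g} >= FAD {fad:.6g} at node {nid}"
            )
        points.append(CalibrationPoint(nid, fad, fad - g))
        true_r[nid] = r
    return points, true_r


def scale_tree(tree: DatedTree, factor: float) -> DatedTree:
    """Multiply all branch lengths (hence ages) by a positive factor."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    from .io_formats import TreeNode

    nodes = {
        nid: TreeNode(
            id=nd.id,
            parent=nd.parent,
            children=list(nd.children),
            length=nd.length * factor,
            age=nd.age * factor,
            label=nd.label,
        )
        for nid, nd in tree.nodes.items()
    }
    return DatedTree(nodes, tree.root_id)


def make_demo_workspace(path, seed: int = 0, n_tips: int = 5) -> dict:
    """Emit a complete, self-consistent demo workspace on disk.

    Contents: a dated Yule tree rescaled to a ~1.5 My root, a founder-style
    scripted slice series (10 slices, 1.8 -> 0 My), per-species occurrence
    records sampled from the true niche on the present slice, a planted
    fossil calibration table, and a ready-to-run ``config.txt``.  Returns a
    manifest dict of the generated pieces.
    """
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    syn = scripted_founder_series(
        seed=int(rng.integers(2**31 - 1)), n_slices=10, age_step=0.2
    )
    raw = simulate_yule_tree(n_tips, birth_rate=1.0, seed=int(rng.integers(2**31 - 1)))
    # root aligned with the scripted corridor so its window brackets the event
    tree = scale_tree(raw, syn.event_age / raw.root.age)
    tree.write(path / "tree.nwk")

    from .io_formats import write_env_series, write_occurrences

    write_env_series(syn.series, path / "slices")

    present = syn.series.youngest()
    frames = []
    for k, sp in enumerate(sorted(tree.tip_ids())):
        tab = sample_occurrences(
            syn.niche,
            present,
            n=25,
            seed=int(rng.integers(2**31 - 1)),
            variables=syn.variables,
            species=sp,
            region_mask=syn.truth_masks[-1],
        )
        frames.append(tab.df)
    table = OccurrenceTable(pd.concat(frames, ignore_index=True))
    write_occurrences(table, path / "occurrences.csv")

    points, true_r = plant_fossils(tree, seed=int(rng.integers(2**31 - 1)))
    pd.DataFrame(
        [{"node_id": p.node_id, "FAD": p.fad, "FAD_min": p.fad_min} for p in points]
    ).to_csv(path / "calibration.csv", index=False, float_format="%.10g")

    config = "\n".join(
        [
            "tree = tree.nwk",
            "occurrences = occurrences.csv",
            "slices_dir = slices",
            "calibration_table = calibration.csv",
            "relative_tree = tree.nwk",
            "background_n = 600",
            "delta = 0.25",
            "age_min = 0.01",
            "age_max = 5.33",
            f"seed = {seed}",
        ]
    )
    (path / "config.txt").write_text(config + "\n")
    return {
        "tree_tips": sorted(tree.tip_ids()),
        "n_occurrences": len(table),
        "slice_ages": syn.series.ages,
        "n_calibrations": len(points),
        "true_r": true_r,
        "scripted_event_age": syn.event_age,
    }


def logistic_niche_fixture(
    seed: int,
    n_presence: int = 500,
    n_background: int = 500,
    n_variables: int = 2,
):
    """Presence/background draws from a known linear+quadratic logistic niche.

    Environment vectors are standard normal; presences are accepted by
    rejection sampling on the true suitability, background is drawn
    unconditionally.  Returns (presence X, background X, niche).
    """
    rng = np.random.default_rng(seed)
    niche = TrueNiche(
        linear=rng.normal(0, 1.5, n_variables),
        quadratic=-np.abs(rng.normal(0.8, 0.3, n_variables)),
        intercept=float(rng.normal(1.0, 0.2)),
    )
    pres = []
    while len(pres) < n_presence:
        X = rng.normal(size=(4 * n_presence, n_variables))
        keep = rng.uniform(size=len(X)) < niche.suitability(X)
        pres.extend(X[keep].tolist())
    presence = np.array(pres[:n_presence])
    background = rng.normal(size=(n_background, n_variables))
    return presence, background, niche
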