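"""Per-node ancestral range projection.

The ancestor at an internal node is assumed to have held the pooled
environmental tolerances of its close descendants (habitat niche
conservatism), so its distribution model is fitted on the union of the
descendants' occurrence records on the present-day slice and projected
onto the paleo slices bracketing the node's age.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import (
    DatedTree,
    EnvSlice,
    EnvSliceSeries,
    OccurrenceTable,
    RasterGrid,
    write_ascii_grid,
)
from .niche_model import NicheModel, predict_suitability

__all__ = [
    "NodeAnalysisWindow",
    "SuitabilitySeries",
    "pooled_occurrences",
    "build_window",
    "project_node",
    "write_series",
]


@dataclass
class NodeAnalysisWindow:
    """The time slices over which a node's divergence is examined."""

    node_id: str
    age_lo: float
    age_hi: float
    delta: float
    slices: list[EnvSlice]   # old -> young

    @property
    def ages(self) -> list[float]:
        return [s.age for s in self.slices]


@dataclass
class SuitabilitySeries:
    """Projected suitability and binarized range per window slice."""

    node_id: str
    tau: float
    ages: list[float]
    suitability: list[RasterGrid]
    range_maps: list[np.ndarray]     # bool, nodata cells are False


def pooled_occurrences(
    tree: DatedTree,
    node_id: str,
    table: OccurrenceTable,
    grid: RasterGrid | None = None,
) -> OccurrenceTable:
    """Union of the records of all tips descending from an internal node.

    With a reference grid, duplicate records within one cell (per species)
    are collapsed.  Descendant tips without any record trigger a warning;
    an entirely empty pool is an error.
    """
    node = tree.nodes.get(node_id)
    if node is None:
        raise KeyError(f"no node {node_id!r} in tree")
    if node.is_tip:
        raise ValueError(f"node {node_id!r} is a tip; pooling needs an internal node")
    tips = tree.descendant_tips(node_id)
    have = set(table.species())
    missing = [t for t in tips if t not in have]
    if missing:
        warnings.warn(
            f"node {node_id}: descendant tip(s) without occurrence records: {missing}",
            RuntimeWarning,
        )
    pooled = table.subset(tips)
    if len(pooled) == 0:
        raise ValueError(f"node {node_id}: no occurrence records for any descendant tip")
    if grid is not None:
        pooled = pooled.dedup_cells(grid)
    return pooled


def build_window(
    tree: DatedTree,
    node_id: str,
    series: EnvSliceSeries,
    delta: float = 0.1,
    age_bounds: tuple[float, float] | None = None,
) -> NodeAnalysisWindow:
    """Slices with age in [age_lo - delta, age_hi + delta], old -> young.

    ``age_bounds`` defaults to the point node age; pass the dating
    credible interval to widen the window before applying delta.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if age_bounds is None:
        a = tree.age(node_id)
        age_bounds = (a, a)
    lo, hi = min(age_bounds), max(age_bounds)
    chosen = series.between(lo - delta, hi + delta)
    if not chosen:
        raise ValueError(
            f"node {node_id}: no slices in window [{lo - delta:g}, {hi + delta:g}] My; "
            f"available ages: {series.ages}"
        )
    return NodeAnalysisWindow(node_id, lo, hi, delta, chosen)


def project_node(
    model: NicheModel, window: NodeAnalysisWindow, tau: float
) -> SuitabilitySeries:
    """Project the fitted model across the window; binarize at >= tau."""
    suits, ranges = [], []
    for s in window.slices:
        grid = predict_suitability(model, s)
        suits.append(grid)
        vals = grid.values
        ranges.append(np.where(np.isfinite(vals), vals >= tau, False))
    return SuitabilitySeries(window.node_id, tau, window.ages, suits, ranges)


def write_series(series: SuitabilitySeries, outdir) -> None:
    """Per-node artifact directory: suitability/range grids + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for age, suit, rng_map in zip(series.ages, series.suitability, series.range_maps):
        s_name, r_name = f"suitability_{age:g}.asc", f"range_{age:g}.asc"
        write_ascii_grid(suit, outdir / s_name)
        write_ascii_grid(
            RasterGrid(rng_map.astype(float), suit.xll, suit.yll, suit.cellsize,
                       suit.nodata),
            outdir / r_name,
        )
        rows.append({"age": age, "suitability": s_name, "range": r_name})
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["age", "suitability", "range"])
        w.writeheader()
        w.writerows(rows)
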