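"""Readers and writers for the formats the pipeline touches.

Dated trees come in as Newick with branch lengths in My and must be
ultrametric; environmental layers are ESRI ASCII grids in geographic
lat/lon; occurrence records are plain CSV with a ``species,lon,lat``
header.  Everything is validated on read and round-trips value-exactly
on write.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import dendropy
import numpy as np
import pandas as pd

ULTRAMETRIC_TOL = 1e-6

__all__ = [
    "DatedTree",
    "TreeNode",
    "RasterGrid",
    "EnvSlice",
    "EnvSliceSeries",
    "OccurrenceTable",
    "read_newick",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_occurrences",
    "write_occurrences",
    "read_env_series",
    "write_env_series",
]


# ---------------------------------------------------------------------------
# Dated trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """One node of a dated tree; ``age`` is in My before present (tips: 0)."""

    id: str
    parent: str | None
    children: list[str]
    length: float
    age: float
    label: str | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children


class DatedTree:
    """Ultrametric phylogeny with node ages in My.

    Node ids are tip labels for leaves and internal Newick labels where
    present, otherwise ``n<k>`` in preorder.  All per-node analyses in the
    pipeline iterate over :meth:`internal_ids`.
    """

    def __init__(self, nodes: dict[str, TreeNode], root_id: str):
        self.nodes = nodes
        self.root_id = root_id
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick_string(cls, text: str) -> "DatedTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=False
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"malformed Newick: {exc}") from exc
        return cls._from_dendropy(dtree)

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree) -> "DatedTree":
        # depths from root, then ultrametricity before committing ages
        root = dtree.seed_node
        depth: dict = {root: 0.0}
        order = []
        for nd in dtree.preorder_node_iter():
            order.append(nd)
            if nd is not root:
                ln = nd.edge.length
                if ln is None:
                    raise ValueError("Newick branch without a numeric length")
                if ln < 0:
                    raise ValueError(f"negative branch length {ln}")
                depth[nd] = depth[nd.parent_node] + float(ln)
        tips = [nd for nd in order if nd.is_leaf()]
        if len(tips) < 2:
            raise ValueError("tree must have at least 2 tips")
        tip_depths = np.array([depth[t] for t in tips])
        lo, hi = tip_depths.argmin(), tip_depths.argmax()
        if tip_depths[hi] - tip_depths[lo] > ULTRAMETRIC_TOL:
            lo_lab = tips[lo].taxon.label if tips[lo].taxon else "?"
            hi_lab = tips[hi].taxon.label if tips[hi].taxon else "?"
            raise ValueError(
                "tree is not ultrametric: root-to-tip lengths differ by "
                f"{tip_depths[hi] - tip_depths[lo]:.6g} between tips "
                f"'{lo_lab}' ({tip_depths[lo]:.6g}) and '{hi_lab}' ({tip_depths[hi]:.6g})"
            )
        height = float(tip_depths.mean())

        nodes: dict[str, TreeNode] = {}
        ids: dict = {}
        k = 0
        for nd in order:
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("unlabeled tip in Newick")
                nid = nd.taxon.label
            elif nd.taxon is not None and nd.taxon.label:
                nid = nd.taxon.label
            elif nd.label:
                nid = nd.label
            else:
                nid = f"n{k}"
            k += 1
            if nid in ids.values():
                raise ValueError(f"duplicate node id {nid!r}")
            ids[nd] = nid
        for nd in order:
            nid = ids[nd]
            age = 0.0 if nd.is_leaf() else height - depth[nd]
            nodes[nid] = TreeNode(
                id=nid,
                parent=ids[nd.parent_node] if nd is not root else None,
                children=[ids[c] for c in nd.child_nodes()],
                length=float(nd.edge.length or 0.0),
                age=age,
                label=nd.taxon.label if nd.taxon else None,
            )
        return cls(nodes, ids[root])

    def _validate(self) -> None:
        for nd in self.nodes.values():
            for c in nd.children:
                if self.nodes[c].age > nd.age + ULTRAMETRIC_TOL:
                    raise ValueError(
                        f"node ages do not decrease rootward->tipward at {nd.id}->{c}"
                    )

    # -- queries ------------------------------------------------------

    @property
    def root(self) -> TreeNode:
        return self.nodes[self.root_id]

    def tip_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.is_tip]

    def internal_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if not n.is_tip]

    def age(self, node_id: str) -> float:
        return self.nodes[node_id].age

    def descendant_tips(self, node_id: str) -> list[str]:
        out: list[str] = []
        stack = [node_id]
        while stack:
            nd = self.nodes[stack.pop()]
            if nd.is_tip:
                out.append(nd.id)
            else:
                stack.extend(reversed(nd.children))
        return out

    # -- output -------------------------------------------------------

    def to_newick(self) -> str:
        def rec(nid: str) -> str:
            nd = self.nodes[nid]
            if nd.is_tip:
                core = nd.id
            else:
                inner = ",".join(rec(c) for c in nd.children)
                core = f"({inner})" + ("" if nd.id.startswith("n") else nd.id)
            if nd.parent is None:
                return core
            return f"{core}:{nd.length:.12g}"

        return rec(self.root_id) + ";"

    def write(self, path: str | os.PathLike) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def read_newick(path: str | os.PathLike) -> DatedTree:
    """Read a dated ultrametric tree from a Newick file."""
    return DatedTree.from_newick_string(Path(path).read_text())


# ---------------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass
class RasterGrid:
    """Corner-registered raster in geographic lat/lon.

    ``values`` is row-major with row 0 the northernmost row; nodata cells
    are stored as NaN and written back using the ``nodata`` sentinel.
    Cell centers sit at ``(xll + (j+0.5)*cellsize, yll + (i_s+0.5)*cellsize)``
    where ``i_s`` counts rows from the south.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D matrix")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def stackable_with(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.xll == other.xll
            and self.yll == other.yll
            and self.cellsize == other.cellsize
        )

    def lon_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        # index 0 = northernmost row, matching the values matrix
        i_s = self.nrows - 1 - np.arange(self.nrows)
        return self.yll + (i_s + 0.5) * self.cellsize

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        i_s = self.nrows - 1 - i
        return (
            self.xll + (j + 0.5) * self.cellsize,
            self.yll + (i_s + 0.5) * self.cellsize,
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Cell whose center is nearest to the point; None if outside extent."""
        j = int(np.floor((lon - self.xll) / self.cellsize))
        i_s = int(np.floor((lat - self.yll) / self.cellsize))
        if j < 0 or j >= self.ncols or i_s < 0 or i_s >= self.nrows:
            return None
        return self.nrows - 1 - i_s, j

    def mask(self) -> np.ndarray:
        """Boolean array of valid (non-nodata) cells."""
        return np.isfinite(self.values)


def read_ascii_grid(path: str | os.PathLike) -> RasterGrid:
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text) and len(header) < 6:
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: ASCII grid header missing keys {missing}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    try:
        data = np.loadtxt(io.StringIO("\n".join(text[i:])), ndmin=2)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse data rows: {exc}") from exc
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data block is {data.shape[0]}x{data.shape[1]}, "
            f"header declares {nrows}x{ncols}"
        )
    nodata = header["nodata_value"]
    vals = np.where(data == nodata, np.nan, data)
    return RasterGrid(
        vals, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata
    )


def write_ascii_grid(grid: RasterGrid, path: str | os.PathLike) -> None:
    out = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll:.17g}\n")
        fh.write(f"yllcorner {grid.yll:.17g}\n")
        fh.write(f"cellsize {grid.cellsize:.17g}\n")
        fh.write(f"NODATA_value {grid.nodata:.17g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Environmental slice series
# ---------------------------------------------------------------------------

@dataclass
class EnvSlice:
    age: float
    variables: dict[str, RasterGrid]

    def grid(self) -> RasterGrid:
        """Any one layer (they are all co-registered)."""
        return next(iter(self.variables.values()))

    def valid_mask(self) -> np.ndarray:
        m = None
        for g in self.variables.values():
            m = g.mask() if m is None else (m & g.mask())
        return m


class EnvSliceSeries:
    """Ordered time slices, each a co-registered stack of named layers.

    Slices are kept old -> young (strictly decreasing ages).
    """

    def __init__(self, slices: Iterable[EnvSlice]):
        self.slices = sorted(slices, key=lambda s: -s.age)
        if not self.slices:
            raise ValueError("empty slice series")
        ages = [s.age for s in self.slices]
        if len(set(ages)) != len(ages):
            raise ValueError(f"duplicate slice ages: {ages}")
        names = set(self.slices[0].variables)
        ref = self.slices[0].grid()
        for s in self.slices:
            if set(s.variables) != names:
                raise ValueError(
                    f"slice {s.age}: variable set {sorted(s.variables)} differs "
                    f"from {sorted(names)}"
                )
            for name, g in s.variables.items():
                if not g.stackable_with(ref):
                    raise ValueError(
                        f"slice {s.age} layer {name} is not co-registered with the series"
                    )

    def __iter__(self) -> Iterator[EnvSlice]:
        return iter(self.slices)

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def ages(self) -> list[float]:
        return [s.age for s in self.slices]

    @property
    def variable_names(self) -> list[str]:
        return sorted(self.slices[0].variables)

    def youngest(self) -> EnvSlice:
        return self.slices[-1]

    def between(self, age_lo: float, age_hi: float) -> list[EnvSlice]:
        """Slices with age in [age_lo, age_hi], old -> young."""
        return [s for s in self.slices if age_lo <= s.age <= age_hi]


def write_env_series(series: EnvSliceSeries, root: str | os.PathLike) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for s in series:
        d = root / f"{s.age:g}"
        d.mkdir(exist_ok=True)
        for name, grid in s.variables.items():
            write_ascii_grid(grid, d / f"{name}.asc")


def read_env_series(root: str | os.PathLike) -> EnvSliceSeries:
    root = Path(root)
    slices = []
    for d in root.iterdir():
        if not d.is_dir():
            continue
        try:
            age = float(d.name)
        except ValueError:
            raise ValueError(f"slice directory {d.name!r} is not named by age")
        variables = {
            f.stem: read_ascii_grid(f) for f in sorted(d.glob("*.asc"))
        }
        if not variables:
            raise ValueError(f"slice directory {d} has no .asc layers")
        slices.append(EnvSlice(age, variables))
    return EnvSliceSeries(slices)


# ---------------------------------------------------------------------------
# Occurrence tables
# ---------------------------------------------------------------------------

class OccurrenceTable:
    """Per-species occurrence records (species id, lon, lat in degrees)."""

    def __init__(self, df: pd.DataFrame):
        required = ["species", "lon", "lat"]
        if list(df.columns[:3]) != required:
            missing = [c for c in required if c not in df.columns]
            if missing:
                raise ValueError(f"occurrence table missing columns {missing}")
            df = df[required]
        df = df.reset_index(drop=True)
        bad_lon = df.index[(df["lon"] < -180) | (df["lon"] > 180)]
        bad_lat = df.index[(df["lat"] < -90) | (df["lat"] > 90)]
        if len(bad_lon) or len(bad_lat):
            # +2: one for the header line, one for 1-based numbering
            lines = sorted(
                [int(i) + 2 for i in bad_lon] + [int(i) + 2 for i in bad_lat]
            )
            raise ValueError(
                f"coordinate out of range at line(s) {lines} "
                "(lon must be in [-180,180], lat in [-90,90])"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def counts(self) -> dict[str, int]:
        return self.df["species"].value_counts().to_dict()

    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    def subset(self, species: Iterable[str]) -> "OccurrenceTable":
        keep = set(species)
        return OccurrenceTable(self.df[self.df["species"].isin(keep)])

    def coords(self) -> np.ndarray:
        return self.df[["lon", "lat"]].to_numpy(float)

    def cells(self, grid: RasterGrid) -> tuple[list[tuple[int, int]], list[int]]:
        """Map each record to its nearest-center grid cell.

        Returns (cells, outside_row_indices); points outside the extent are
        flagged, never silently dropped.
        """
        cells: list[tuple[int, int]] = []
        outside: list[int] = []
        for idx, (lon, lat) in enumerate(self.coords()):
            c = grid.cell_of(lon, lat)
            if c is None:
                outside.append(idx)
            else:
                cells.append(c)
        return cells, outside

    def dedup_cells(self, grid: RasterGrid) -> "OccurrenceTable":
        """Collapse records falling in the same grid cell (per species)."""
        seen: set = set()
        keep_rows = []
        for idx, row in self.df.iterrows():
            c = grid.cell_of(row["lon"], row["lat"])
            key = (row["species"], c)
            if c is not None and key in seen:
                continue
            seen.add(key)
            keep_rows.append(idx)
        return OccurrenceTable(self.df.loc[keep_rows])

    def unmatched_species(self, tree: DatedTree) -> list[str]:
        tips = set(tree.tip_ids())
        return [s for s in self.species() if s not in tips]


def read_occurrences(path: str | os.PathLike) -> OccurrenceTable:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return OccurrenceTable(df)


def write_occurrences(table: OccurrenceTable, path: str | os.PathLike) -> None:
    table.df.to_csv(path, index=False, float_format="%.17g")
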