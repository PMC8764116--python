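"""End-to-end orchestration: per-node analyses over the whole tree.

``run_node`` chains pooled occurrences -> niche model fit on the present
slice -> paleo projection over the node's window -> occupancy propagation
-> event detection -> scenario classification, writing all artifacts.
``run_all`` batches this over every internal node dated inside a given
interval (default Pliocene-Pleistocene).  Runs are fully determined by
(config, seed): reports are byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import fragmentation as frag
from . import niche_model as nm
from . import paleoprojection as pp
from .io_formats import (
    DatedTree,
    EnvSliceSeries,
    OccurrenceTable,
    read_env_series,
    read_newick,
    read_occurrences,
)

log = logging.getLogger("paleorange")

__all__ = ["RunConfig", "Workspace", "run_node", "run_all", "run_calibration"]

# Pliocene-Pleistocene bounds in My; the default set of analysed nodes
PLIO_PLEISTOCENE = (0.01, 5.33)


@dataclass
class RunConfig:
    """Flat, fully logged run configuration.

    Paths are resolved relative to the config file's directory when read
    from disk.  Unknown keys in a config file are rejected.
    """

    tree: str = "tree.nwk"
    occurrences: str = "occurrences.csv"
    slices_dir: str = "slices"
    calibration_table: str = ""
    relative_tree: str = ""
    threshold_rule: str = "max_sens_plus_spec"
    tau: float | None = None          # overrides the rule when set
    beta: float = 1.0
    feature_classes: str = "linear,quadratic,hinge"
    background_n: int = 10_000
    adjacency: str = "rook"
    dispersal_radius: int = 1
    delta: float = 0.1
    q: float = 0.95
    scale_method: str = "chronogram"  # or "min"/"corrected" for undated trees
    age_min: float = PLIO_PLEISTOCENE[0]
    age_max: float = PLIO_PLEISTOCENE[1]
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        known = {f.name: f for f in dc_fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = known[key].type
            if key == "tau":
                kwargs[key] = None if val.lower() in ("", "none") else float(val)
            elif typ == "int":
                kwargs[key] = int(val)
            elif typ == "float":
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        base = path.parent
        for key in ("tree", "occurrences", "slices_dir", "calibration_table",
                    "relative_tree"):
            v = getattr(cfg, key)
            if v:
                setattr(cfg, key, str((base / v)))
        return cfg

    def to_text(self) -> str:
        lines = []
        for f in dc_fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {'' if v is None else v}")
        return "\n".join(lines) + "\n"

    def hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]

    def classes(self) -> tuple[str, ...]:
        return tuple(s.strip() for s in self.feature_classes.split(",") if s.strip())


@dataclass
class Workspace:
    tree: DatedTree
    occurrences: OccurrenceTable
    series: EnvSliceSeries

    @classmethod
    def load(cls, cfg: RunConfig) -> "Workspace":
        return cls(
            tree=read_newick(cfg.tree),
            occurrences=read_occurrences(cfg.occurrences),
            series=read_env_series(cfg.slices_dir),
        )


def _node_seed(seed: int, node_id: str) -> int:
    # stable per-node stream independent of iteration order
    return (int(seed) * 1_000_003 + zlib.crc32(node_id.encode())) % (2**31 - 1)


@dataclass
class NodeResult:
    scenario: frag.SpeciationScenario
    auc: float
    tau: float
    n_presence: int
    n_background: int
    window_ages: list[float]
    node_age: float

    def row(self) -> dict:
        sc = self.scenario
        return {
            "node_id": sc.node_id,
            "node_age": self.node_age,
            "verdict": sc.verdict,
            "event_age_lo": sc.event_age_lo,
            "event_age_hi": sc.event_age_hi,
            "auc": self.auc,
            "tau": self.tau,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "n_slices": len(self.window_ages),
            "note": sc.note,
        }


def run_node(
    cfg: RunConfig,
    ws: Workspace,
    node_id: str,
    outdir=None,
) -> NodeResult:
    """The full per-node chain; artifacts written under ``outdir`` if given."""
    present = ws.series.youngest()
    ref_grid = present.grid()
    variables = ws.series.variable_names

    def stage(name):
        log.info("node %s: %s", node_id, name)

    try:
        stage("pooling descendant occurrences")
        pooled = pp.pooled_occurrences(ws.tree, node_id, ws.occurrences, grid=ref_grid)
        stage("extracting environment")
        X_pres, _rep = nm.extract_env(pooled, present, variables)
        n_bg = min(cfg.background_n, int(present.valid_mask().sum()))
        X_bg, _cells = nm.sample_background(
            present, n_bg, _node_seed(cfg.seed, node_id), variables
        )
        stage("fitting niche model")
        model = nm.fit_model(
            X_pres, X_bg, variables, classes=cfg.classes(), beta=cfg.beta
        )
        report = nm.evaluate(model, X_pres, X_bg, cfg.threshold_rule)
        tau = cfg.tau if cfg.tau is not None else report.threshold
        stage("building window and projecting")
        window = pp.build_window(ws.tree, node_id, ws.series, delta=cfg.delta)
        proj = pp.project_node(model, window, tau)
        stage("propagating occupancy and detecting events")
        cells, _outside = pooled.cells(ref_grid)
        if len(window.slices) >= 2:
            occ = frag.build_occupancy(
                proj.range_maps, proj.ages, cells,
                dispersal_radius=cfg.dispersal_radius, adjacency=cfg.adjacency,
            )
            events = frag.detect_events(occ)
            scenario = frag.classify_scenario(node_id, events)
        else:
            scenario = frag.SpeciationScenario(
                node_id, "none", note="window has a single slice; no transitions"
            )
            events = []
    except Exception as exc:
        raise RuntimeError(f"node {node_id}: {exc}") from exc

    result = NodeResult(
        scenario=scenario,
        auc=report.auc,
        tau=tau,
        n_presence=len(X_pres),
        n_background=n_bg,
        window_ages=window.ages,
        node_age=ws.tree.age(node_id),
    )
    if outdir is not None:
        outdir = Path(outdir)
        pp.write_series(proj, outdir)
        _write_events(events, node_id, outdir / "events.csv")
        pd.DataFrame([result.row()]).to_csv(
            outdir / "scenario.csv", index=False, float_format="%.10g"
        )
        (outdir / "config_hash.txt").write_text(cfg.hash() + "\n")
    return result


def _write_events(events, node_id, path) -> None:
    rows = [
        {
            "node_id": node_id,
            "slice_age": e.age,
            "event_type": e.kind,
            "components": repr(e.components),
            "detail": repr({k: v for k, v in e.detail.items()}),
        }
        for e in events
    ]
    pd.DataFrame(
        rows, columns=["node_id", "slice_age", "event_type", "components", "detail"]
    ).to_csv(path, index=False, float_format="%.10g")


def run_all(cfg: RunConfig, ws: Workspace | None = None, outdir=None) -> pd.DataFrame:
    """One scenario row per internal node with age in [age_min, age_max].

    Per-node failures are recorded (verdict ``error``) and the run
    continues; the result is independent of node iteration order.
    """
    if ws is None:
        ws = Workspace.load(cfg)
    nodes = sorted(
        n for n in ws.tree.internal_ids()
        if cfg.age_min <= ws.tree.age(n) <= cfg.age_max
    )
    rows = []
    for nid in nodes:
        node_out = None if outdir is None else Path(outdir) / f"node_{nid}"
        try:
            res = run_node(cfg, ws, nid, outdir=node_out)
            rows.append(res.row())
        except Exception as exc:
            log.error("%s", exc)
            rows.append(
                {
                    "node_id": nid,
                    "node_age": ws.tree.age(nid),
                    "verdict": "error",
                    "note": str(exc),
                }
            )
    cols = ["node_id", "node_age", "verdict", "event_age_lo", "event_age_hi",
            "auc", "tau", "n_presence", "n_background", "n_slices", "note"]
    df = pd.DataFrame(rows).reindex(columns=cols).sort_values("node_id")
    df = df.reset_index(drop=True)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "scenarios.csv", index=False, float_format="%.10g")
        (outdir / "config_hash.txt").write_text(cfg.hash() + "\n")
        (outdir / "config_resolved.txt").write_text(cfg.to_text())
    return df


def run_calibration(cfg: RunConfig, outdir=None):
    """Ghost-lineage prior construction from the calibration table.

    Needs ``calibration_table`` (node_id,FAD,FAD_min CSV) and
    ``relative_tree`` (Newick whose node depths give relative heights).
    Returns (densities, fitted model, s_min).
    """
    if not cfg.calibration_table:
        raise ValueError("config has no calibration_table path")
    if not cfg.relative_tree:
        raise ValueError("config has no relative_tree path")
    points = cal.read_calibration_table(cfg.calibration_table)
    rel_tree = read_newick(cfg.relative_tree)
    heights = {nid: rel_tree.age(nid) for nid in rel_tree.internal_ids()}
    if cfg.scale_method == "chronogram":
        s_min = 1.0
        r, excluded = cal.ghost_times_from_chronogram(heights, points)
    else:
        if cfg.scale_method == "corrected":
            s_min = cal.corrected_scale_factor(heights, points)
        elif cfg.scale_method == "min":
            s_min = cal.min_scale_factor(heights, points)
        else:
            raise ValueError(f"unknown scale_method {cfg.scale_method!r}")
        r, excluded = cal.relative_ghost_times(s_min, heights, points)
    model = cal.fit_ghost_distribution(r, q=cfg.q)
    model.excluded = excluded
    densities = [cal.build_prior(p, model) for p in points]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cal.write_densities(densities, outdir / "calibration_densities.csv")
        summary = pd.DataFrame(
            [{
                "s_min": s_min,
                "mean_r": model.mean_r,
                "var_r": model.var_r,
                "meanlog": model.meanlog,
                "sdlog": model.sdlog,
                "q": model.q,
                "n_used": model.n_used,
                "n_excluded": len(excluded),
            }]
        )
        summary.to_csv(outdir / "ghost_model.csv", index=False, float_format="%.10g")
    return densities, model, s_min
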