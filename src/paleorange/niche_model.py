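"""Presence/background species distribution model.

A maximum-entropy-style SDM: environmental variables are expanded into
linear / quadratic / product / hinge features (standardized on the
training sample), and the feature weights maximize the L1-penalized
presence-vs-background logistic log-likelihood — the standard
correspondence between MaxEnt with lasso regularization and penalized
logistic regression on the expanded feature space.  Output is the
logistic (sigmoid) transform, guaranteed in [0, 1].

Evaluation follows the usual SDM reporting: rank-based AUC of presences
against background, and a binarization threshold tau chosen by a named
rule (maximum sensitivity+specificity, minimum presence score, or a
presence percentile).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .io_formats import EnvSlice, OccurrenceTable, RasterGrid

__all__ = [
    "FeatureExpansion",
    "NicheModel",
    "EvalReport",
    "extract_env",
    "sample_background",
    "fit_model",
    "predict_suitability",
    "compute_auc",
    "select_threshold",
]

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

class FeatureExpansion:
    """Standardization + feature construction, frozen at fit time.

    Hinge features are forward and reverse ramps at knots placed at
    training quantiles of each standardized variable, so fitting is
    invariant to affine transforms of the raw inputs.
    """

    def __init__(self, classes: Sequence[str] = ("linear", "quadratic", "hinge"),
                 n_hinge_knots: int = 4):
        bad = [c for c in classes if c not in FEATURE_CLASSES]
        if bad:
            raise ValueError(f"unknown feature classes {bad}; allowed {FEATURE_CLASSES}")
        if not classes:
            raise ValueError("at least one feature class required")
        self.classes = tuple(classes)
        self.n_hinge_knots = n_hinge_knots
        self.means_: np.ndarray | None = None
        self.sds_: np.ndarray | None = None
        self.knots_: np.ndarray | None = None  # (n_vars, n_knots) on the z scale

    def fit(self, X: np.ndarray) -> "FeatureExpansion":
        X = np.asarray(X, dtype=float)
        self.means_ = X.mean(axis=0)
        sds = X.std(axis=0)
        self.sds_ = np.where(sds > 0, sds, 1.0)
        if "hinge" in self.classes:
            Z = (X - self.means_) / self.sds_
            qs = np.linspace(0, 100, self.n_hinge_knots + 2)[1:-1]
            self.knots_ = np.percentile(Z, qs, axis=0).T
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("expansion not fitted")
        X = np.asarray(X, dtype=float)
        Z = (X - self.means_) / self.sds_
        cols = []
        if "linear" in self.classes:
            cols.append(Z)
        if "quadratic" in self.classes:
            cols.append(Z**2)
        if "product" in self.classes:
            n = Z.shape[1]
            for i in range(n):
                for j in range(i + 1, n):
                    cols.append((Z[:, i] * Z[:, j])[:, None])
        if "hinge" in self.classes:
            for v in range(Z.shape[1]):
                for k in self.knots_[v]:
                    cols.append(np.maximum(Z[:, v] - k, 0.0)[:, None])
                    cols.append(np.maximum(k - Z[:, v], 0.0)[:, None])
        return np.hstack(cols)

    def feature_names(self, variables: Sequence[str]) -> list[str]:
        names: list[str] = []
        if "linear" in self.classes:
            names += list(variables)
        if "quadratic" in self.classes:
            names += [f"{v}^2" for v in variables]
        if "product" in self.classes:
            for i in range(len(variables)):
                for j in range(i + 1, len(variables)):
                    names.append(f"{variables[i]}*{variables[j]}")
        if "hinge" in self.classes:
            for v_i, v in enumerate(variables):
                for k in self.knots_[v_i]:
                    names.append(f"hinge+({v},{k:.6g})")
                    names.append(f"hinge-({v},{k:.6g})")
        return names


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class NicheModel:
    variables: list[str]
    expansion: FeatureExpansion
    weights: np.ndarray
    intercept: float
    beta: float
    n_presence: int
    n_background: int
    converged: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Suitability in [0,1] for raw environment vectors (rows)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        A = self.expansion.transform(X)
        return expit(A @ self.weights + self.intercept)

    # plain-text round-trip serialization -----------------------------

    def to_text(self) -> str:
        lines = [
            f"variables={','.join(self.variables)}",
            f"classes={','.join(self.expansion.classes)}",
            f"n_hinge_knots={self.expansion.n_hinge_knots}",
            f"beta={self.beta:.17g}",
            f"intercept={self.intercept:.17g}",
            f"n_presence={self.n_presence}",
            f"n_background={self.n_background}",
            "means=" + ",".join(f"{v:.17g}" for v in self.expansion.means_),
            "sds=" + ",".join(f"{v:.17g}" for v in self.expansion.sds_),
            "weights=" + ",".join(f"{v:.17g}" for v in self.weights),
        ]
        if self.expansion.knots_ is not None:
            for i, row in enumerate(self.expansion.knots_):
                lines.append(f"knots{i}=" + ",".join(f"{v:.17g}" for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "NicheModel":
        kv = dict(line.split("=", 1) for line in text.strip().splitlines())
        exp = FeatureExpansion(
            classes=tuple(kv["classes"].split(",")),
            n_hinge_knots=int(kv["n_hinge_knots"]),
        )
        exp.means_ = np.array([float(v) for v in kv["means"].split(",")])
        exp.sds_ = np.array([float(v) for v in kv["sds"].split(",")])
        variables = kv["variables"].split(",")
        if "hinge" in exp.classes:
            exp.knots_ = np.array(
                [
                    [float(v) for v in kv[f"knots{i}"].split(",")]
                    for i in range(len(variables))
                ]
            )
        return cls(
            variables=variables,
            expansion=exp,
            weights=np.array([float(v) for v in kv["weights"].split(",")]),
            intercept=float(kv["intercept"]),
            beta=float(kv["beta"]),
            n_presence=int(kv["n_presence"]),
            n_background=int(kv["n_background"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "NicheModel":
        return cls.from_text(Path(path).read_text())


@dataclass
class EvalReport:
    auc: float
    threshold: float
    rule: str
    output_transform: str = "logistic"


# ---------------------------------------------------------------------------
# Environment extraction and background sampling
# ---------------------------------------------------------------------------

def extract_env(
    points: OccurrenceTable, env_slice: EnvSlice, variables: Sequence[str] | None = None
) -> tuple[np.ndarray, dict]:
    """One environment vector per record; nodata/outside points dropped.

    Returns (matrix n_kept x n_vars, report) where report counts the
    records excluded for falling outside the extent or on nodata cells.
    """
    variables = list(variables or sorted(env_slice.variables))
    grid = env_slice.variables[variables[0]]
    vecs, kept = [], []
    n_outside = n_nodata = 0
    for idx, (lon, lat) in enumerate(points.coords()):
        c = grid.cell_of(lon, lat)
        if c is None:
            n_outside += 1
            continue
        v = np.array([env_slice.variables[name].values[c] for name in variables])
        if not np.all(np.isfinite(v)):
            n_nodata += 1
            continue
        vecs.append(v)
        kept.append(idx)
    if not vecs:
        raise ValueError(
            f"no usable occurrence points: {n_outside} outside extent, "
            f"{n_nodata} on nodata cells"
        )
    report = {"n_kept": len(vecs), "n_outside": n_outside, "n_nodata": n_nodata,
              "kept_rows": kept}
    return np.vstack(vecs), report


def sample_background(
    env_slice: EnvSlice,
    n: int,
    rng: np.random.Generator | int,
    variables: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample of n distinct valid cells; returns (vectors, cell ids).

    Cell ids are flat row-major indices into the slice grids.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    variables = list(variables or sorted(env_slice.variables))
    valid = env_slice.valid_mask()
    flat = np.flatnonzero(valid.ravel())
    if n > len(flat):
        raise ValueError(f"requested {n} background cells, only {len(flat)} valid")
    chosen = np.sort(rng.choice(flat, size=n, replace=False))
    nrows, ncols = valid.shape
    ii, jj = np.unravel_index(chosen, (nrows, ncols))
    X = np.column_stack(
        [env_slice.variables[name].values[ii, jj] for name in variables]
    )
    return X, chosen


# ---------------------------------------------------------------------------
# Fitting: L1-penalized logistic via FISTA with adaptive restart
# ---------------------------------------------------------------------------

def _l1_logistic(A: np.ndarray, y: np.ndarray, beta: float,
                 tol: float = 1e-6, max_iter: int = 10_000):
    """Minimize sum_i log(1+e^{m_i}) - y_i m_i + beta*||w||_1, m = A w + b.

    Proximal-gradient (FISTA) with the intercept unpenalized; convergence
    when the minimal-norm subgradient falls below ``tol``.
    Returns (w, b, converged, final_norm).
    """
    n, p = A.shape
    X = np.hstack([A, np.ones((n, 1))])
    # Lipschitz constant of the logistic gradient
    L = 0.25 * np.linalg.norm(X, 2) ** 2
    w = np.zeros(p + 1)
    v = w.copy()
    t_k = 1.0
    f_prev = np.inf

    def objective(u):
        m = X @ u
        return float(np.sum(np.logaddexp(0.0, m) - y * m) + beta * np.abs(u[:p]).sum())

    def subgrad_norm(u):
        g = X.T @ (expit(X @ u) - y)
        r = np.empty(p + 1)
        nz = u[:p] != 0
        r[:p][nz] = g[:p][nz] + beta * np.sign(u[:p][nz])
        r[:p][~nz] = np.maximum(np.abs(g[:p][~nz]) - beta, 0.0)
        r[p] = g[p]
        return float(np.linalg.norm(r))

    norm = subgrad_norm(w)
    for _ in range(max_iter):
        if norm < tol:
            return w[:p], w[p], True, norm
        g = X.T @ (expit(X @ v) - y)
        z = v - g / L
        wn = z.copy()
        wn[:p] = np.sign(z[:p]) * np.maximum(np.abs(z[:p]) - beta / L, 0.0)
        f_new = objective(wn)
        if f_new > f_prev:       # adaptive restart of the momentum
            t_k = 1.0
            v = w.copy()
            g = X.T @ (expit(X @ v) - y)
            z = v - g / L
            wn = z.copy()
            wn[:p] = np.sign(z[:p]) * np.maximum(np.abs(z[:p]) - beta / L, 0.0)
            f_new = objective(wn)
        t_next = (1.0 + math.sqrt(1.0 + 4.0 * t_k**2)) / 2.0
        v = wn + ((t_k - 1.0) / t_next) * (wn - w)
        w, t_k, f_prev = wn, t_next, f_new
        norm = subgrad_norm(w)
    return w[:p], w[p], norm < tol, norm


def fit_model(
    presence: np.ndarray,
    background: np.ndarray,
    variables: Sequence[str],
    classes: Sequence[str] = ("linear", "quadratic", "hinge"),
    beta: float = 1.0,
    n_hinge_knots: int = 4,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> NicheModel:
    """Fit the penalized presence/background model.

    ``beta`` is the L1 regularization multiplier (0 = unpenalized); the
    intercept is never penalized.  Standardization constants and hinge
    knots come from the pooled training sample only.
    """
    presence = np.atleast_2d(np.asarray(presence, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if len(presence) < 5:
        raise ValueError(f"need at least 5 presence records, got {len(presence)}")
    if beta < 0:
        raise ValueError("regularization multiplier beta must be >= 0")
    X = np.vstack([presence, background])
    y = np.concatenate([np.ones(len(presence)), np.zeros(len(background))])
    exp = FeatureExpansion(classes, n_hinge_knots).fit(X)
    A = exp.transform(X)
    w, b, ok, norm = _l1_logistic(A, y, beta, tol=tol, max_iter=max_iter)
    if not ok:
        warnings.warn(
            f"niche model fit did not reach gradient norm {tol:g} "
            f"(final {norm:.3g} after {max_iter} iterations)",
            RuntimeWarning,
        )
    return NicheModel(
        variables=list(variables),
        expansion=exp,
        weights=w,
        intercept=b,
        beta=beta,
        n_presence=len(presence),
        n_background=len(background),
        converged=ok,
    )


# ---------------------------------------------------------------------------
# Projection and evaluation
# ---------------------------------------------------------------------------

def predict_suitability(model: NicheModel, env_slice: EnvSlice) -> RasterGrid:
    """Per-cell suitability map; nodata in any layer propagates."""
    missing = [v for v in model.variables if v not in env_slice.variables]
    if missing:
        raise ValueError(f"slice at {env_slice.age} My lacks variable(s) {missing}")
    ref = env_slice.grid()
    stack = np.stack([env_slice.variables[v].values for v in model.variables], axis=-1)
    flat = stack.reshape(-1, len(model.variables))
    valid = np.all(np.isfinite(flat), axis=1)
    out = np.full(flat.shape[0], np.nan)
    if valid.any():
        out[valid] = model.predict(flat[valid])
    return RasterGrid(
        out.reshape(ref.values.shape), ref.xll, ref.yll, ref.cellsize, ref.nodata
    )


def compute_auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), ties counted one half."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2.0
    return float(u / (len(p) * len(b)))


def select_threshold(
    presence_scores: np.ndarray,
    background_scores: np.ndarray,
    rule: str = "max_sens_plus_spec",
) -> float:
    """Binarization threshold tau by a named rule.

    Rules: ``max_sens_plus_spec`` (Youden's J, midpoint of the optimal
    interval), ``min_presence`` (lowest presence score), or
    ``presence_percentile:<p>``.
    """
    p = np.sort(np.asarray(presence_scores, dtype=float))
    b = np.sort(np.asarray(background_scores, dtype=float))
    if rule == "min_presence":
        return float(p[0])
    if rule.startswith("presence_percentile"):
        try:
            pct = float(rule.split(":", 1)[1])
        except (IndexError, ValueError):
            raise ValueError(
                f"rule {rule!r} needs a percentile, e.g. 'presence_percentile:10'"
            )
        return float(np.percentile(p, pct))
    if rule == "max_sens_plus_spec":
        cand = np.unique(np.concatenate([p, b]))
        # J(tau) = TPR - FPR with the >= tau decision rule
        tpr = 1.0 - np.searchsorted(p, cand, side="left") / len(p)
        fpr = 1.0 - np.searchsorted(b, cand, side="left") / len(b)
        j = tpr - fpr
        best = int(np.argmax(j))
        tau = cand[best]
        if best > 0:
            tau = (cand[best - 1] + cand[best]) / 2.0  # midpoint of optimal interval
        return float(tau)
    raise ValueError(f"unknown threshold rule {rule!r}")


def evaluate(
    model: NicheModel,
    presence: np.ndarray,
    background: np.ndarray,
    rule: str = "max_sens_plus_spec",
) -> EvalReport:
    ps = model.predict(presence)
    bs = model.predict(background)
    return EvalReport(
        auc=compute_auc(ps, bs),
        threshold=select_threshold(ps, bs, rule),
        rule=rule,
    )
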