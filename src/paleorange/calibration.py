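"""Fossil-calibration priors from ghost-lineage times.

A fossil first appearance datum (FAD) only bounds a node age from below;
the gap between the true divergence time Td and the FAD is the ghost
lineage g = Td - FAD.  Assuming the *relative* ghost time r = g / FAD is
identically distributed across nodes whose fossil record is reasonably
complete (FAD > Td/2, i.e. r < 1), the r distribution estimated from the
available calibrations yields a soft maximum for every calibrated node:
the prior on Td is an offset lognormal anchored at the hard minimum
FAD_min (base of the FAD's stratigraphic zone) and the soft maximum is
its upper quantile q.

The scale bridging relative node heights and absolute FADs is the
minimal stratigraphically consistent one (a bracketing argument in the
spirit of Marshall's fossil-gap method), avoiding any circular dating
loop.

Also provided: the ordinary-least-squares correction for ancestral
polymorphism — regressing gene-tree (concatenation) node ages on relative
species divergence times; the intercept is the mean interval between
allele and species divergence.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationPoint",
    "GhostLineageModel",
    "CalibrationDensity",
    "min_scale_factor",
    "corrected_scale_factor",
    "ghost_times_from_chronogram",
    "relative_ghost_times",
    "fit_ghost_distribution",
    "build_prior",
    "polymorphism_correction",
    "read_calibration_table",
    "write_densities",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """A fossil calibration: FAD and the base of its stratigraphic zone."""

    node_id: str
    fad: float        # first appearance datum, My
    fad_min: float    # hard minimum constraint, My

    def __post_init__(self):
        if not (0 < self.fad_min <= self.fad):
            raise ValueError(
                f"{self.node_id}: require 0 < FAD_min <= FAD, "
                f"got FAD_min={self.fad_min}, FAD={self.fad}"
            )


@dataclass
class GhostLineageModel:
    """Fitted distribution of relative ghost times r = (Td - FAD)/FAD."""

    family: str
    mean_r: float
    var_r: float
    meanlog: float | None
    sdlog: float | None
    q: float
    n_used: int
    excluded: list[str] = field(default_factory=list)
    degenerate: bool = False


@dataclass
class CalibrationDensity:
    """Offset-lognormal prior on a node age Td, zero below the hard minimum."""

    node_id: str
    hard_min: float
    soft_max: float
    offset: float      # equals hard_min
    meanlog: float
    sdlog: float
    q: float

    def density(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        inside = t > self.offset
        if self.sdlog == 0:
            return out  # point mass; density is a delta, reported as 0
        out[inside] = stats.lognorm.pdf(
            t[inside] - self.offset, s=self.sdlog, scale=math.exp(self.meanlog)
        )
        return out

    def quantile(self, p: float) -> float:
        if self.sdlog == 0:
            return self.offset + math.exp(self.meanlog)
        return self.offset + float(
            stats.lognorm.ppf(p, s=self.sdlog, scale=math.exp(self.meanlog))
        )


def min_scale_factor(
    relative_heights: Mapping[str, float], points: Sequence[CalibrationPoint]
) -> float:
    """Smallest scale s (My per unit height) with s*h_i >= FAD_i for all i.

    Any smaller scale would place at least one divergence younger than its
    fossil; this is the bracketing lower edge of stratigraphic consistency.
    """
    if not points:
        raise ValueError("empty calibration set")
    s = 0.0
    for p in points:
        h = relative_heights.get(p.node_id)
        if h is None:
            raise KeyError(f"no relative height for calibrated node {p.node_id!r}")
        if h <= 0:
            raise ValueError(f"non-positive relative height for node {p.node_id!r}")
        s = max(s, p.fad / h)
    return s


def _expected_min_lognormal(meanlog: float, sdlog: float, n: int) -> float:
    """E[min of n iid lognormal draws], by quadrature of the survival power."""
    if sdlog == 0:
        return math.exp(meanlog)
    from scipy import integrate

    scale = math.exp(meanlog)
    upper = float(stats.lognorm.ppf(0.999, s=sdlog, scale=scale))
    val, _ = integrate.quad(
        lambda x: stats.lognorm.sf(x, s=sdlog, scale=scale) ** n,
        0.0,
        upper,
        limit=200,
    )
    return float(val)


def _min_functionals(meanlog: float, sdlog: float, n: int) -> tuple[float, float, float]:
    """(E[m], E[1/(1+m)], E[1/(1+m)^2]) for m = min of n iid lognormals.

    The minimum has density n * sf(x)^(n-1) * pdf(x); the integrals are
    evaluated by quadrature over the region where the survival power is
    non-negligible.
    """
    from scipy import integrate

    scale = math.exp(meanlog)
    upper = float(stats.lognorm.ppf(min(0.9999, 60.0 / n), s=sdlog, scale=scale))

    def dens(x):
        sf = stats.lognorm.sf(x, s=sdlog, scale=scale)
        return n * sf ** (n - 1) * stats.lognorm.pdf(x, s=sdlog, scale=scale)

    e_min = integrate.quad(lambda x: x * dens(x), 0, upper, limit=200)[0]
    i1 = integrate.quad(lambda x: dens(x) / (1 + x), 0, upper, limit=200)[0]
    i2 = integrate.quad(lambda x: dens(x) / (1 + x) ** 2, 0, upper, limit=200)[0]
    # renormalize for the truncated integration range
    z = integrate.quad(dens, 0, upper, limit=200)[0]
    if z <= 0:
        raise FloatingPointError("degenerate minimum distribution")
    return e_min / z, i1 / z, i2 / z


def corrected_scale_factor(
    relative_heights: Mapping[str, float],
    points: Sequence[CalibrationPoint],
) -> float:
    """Bracketing scale corrected for the expected gap of the best fossil.

    The minimal consistent scale s_min forces the tightest calibration's
    ghost time to exactly zero, which depresses every relative ghost time
    by the smallest relative gap in the sample (even the best fossil
    postdates its divergence).  The normalization bias is modelled
    explicitly: if r ~ Lognormal(mu, sigma) with mean m and variance v,
    the ghost times implied by s_min have approximately

        E[mean] = (1 + m) * E[1/(1 + g)] - 1,   E[var] = v * E[1/(1 + g)^2],

    with g the minimum of n draws.  Solving these two equations for
    (mu, sigma) from the observed s_min-normalized moments and returning
    s = s_min * (1 + E[g]) de-biases the scale — a gap correction in the
    stratigraphic-confidence-interval tradition, not an iterated dating
    loop.  Falls back to s_min when the solve fails or n < 3.
    """
    from scipy.optimize import least_squares

    s_min = min_scale_factor(relative_heights, points)
    n = len(points)
    if n < 3:
        return s_min
    ratios = np.array([relative_heights[p.node_id] / p.fad for p in points])
    r0 = s_min * ratios - 1.0
    a, b = float(r0.mean()), float(r0.var(ddof=1))
    if a <= 0 or b <= 0:
        return s_min

    def residuals(theta):
        meanlog, logsd = theta
        sdlog = math.exp(logsd)
        try:
            _, i1, i2 = _min_functionals(meanlog, sdlog, n)
        except FloatingPointError:
            return [1e3, 1e3]
        m = math.exp(meanlog + sdlog**2 / 2.0)
        v = m**2 * math.expm1(sdlog**2)
        return [((1 + m) * i1 - 1) - a, v * i2 - b]

    # start from the naive moment fit of the (biased) normalized sample
    ml0, sd0 = _lognormal_moment_match(max(a, 1e-6), b)
    try:
        sol = least_squares(
            residuals,
            x0=[ml0, math.log(max(sd0, 1e-3))],
            bounds=([-10.0, math.log(1e-3)], [3.0, math.log(3.0)]),
            xtol=1e-12,
            ftol=1e-12,
        )
        if not sol.success or np.linalg.norm(sol.fun) > 1e-3 * max(a, b):
            return s_min
        meanlog, sdlog = sol.x[0], math.exp(sol.x[1])
        e_min, _, _ = _min_functionals(meanlog, sdlog, n)
        return s_min * (1.0 + e_min)
    except Exception:
        return s_min


def ghost_times_from_chronogram(
    node_ages: Mapping[str, float], points: Sequence[CalibrationPoint]
) -> tuple[dict[str, float], list[str]]:
    """Relative ghost times when node ages are already in My.

    This is the preferred workflow: with a dated chronogram the scale is
    known (s = 1) and r = (Td - FAD)/FAD is computed directly; the
    bracketing scale is only checked for stratigraphic consistency (every
    fossil must be younger than its node).  Estimating the scale from the
    same FADs (see :func:`corrected_scale_factor`) is weakly identified
    and should be reserved for genuinely undated trees.
    """
    s_min = min_scale_factor(node_ages, points)
    if s_min > 1.0 + 1e-9:
        bad = max(points, key=lambda p: p.fad / node_ages[p.node_id])
        raise ValueError(
            "chronogram is stratigraphically inconsistent: node "
            f"{bad.node_id} at {node_ages[bad.node_id]:.6g} My is younger than "
            f"its fossil FAD {bad.fad:.6g} My"
        )
    return relative_ghost_times(1.0, node_ages, points)


def relative_ghost_times(
    s: float,
    relative_heights: Mapping[str, float],
    points: Sequence[CalibrationPoint],
) -> tuple[dict[str, float], list[str]]:
    """r_i = (s*h_i - FAD_i)/FAD_i per node; nodes with r >= 1 are excluded.

    The exclusion implements the completeness condition FAD > Td/2: the
    relative-ghost-time distribution is only assumed shared among nodes
    whose fossil record covers more than half the lineage duration.
    Returns (retained r by node id, excluded node ids).
    """
    r: dict[str, float] = {}
    excluded: list[str] = []
    for p in points:
        h = relative_heights[p.node_id]
        ri = (s * h - p.fad) / p.fad
        if ri < -1e-12:
            raise ValueError(
                f"scale {s} is below the minimal consistent scale: node "
                f"{p.node_id} gets Td={s * h:.6g} < FAD={p.fad:.6g}"
            )
        ri = max(ri, 0.0)
        if ri >= 1.0:
            excluded.append(p.node_id)
        else:
            r[p.node_id] = ri
    return r, excluded


def _lognormal_moment_match(mean: float, var: float) -> tuple[float, float]:
    """(meanlog, sdlog) of the lognormal with the given mean and variance."""
    if mean <= 0:
        raise ValueError("moment matching needs a positive mean")
    sd2 = math.log1p(var / mean**2)
    return math.log(mean) - sd2 / 2.0, math.sqrt(sd2)


def fit_ghost_distribution(
    r_values: Mapping[str, float] | Sequence[float],
    family: str = "lognormal",
    q: float = 0.95,
    method: str = "moments",
) -> GhostLineageModel:
    """Fit the relative-ghost-time distribution from retained r values.

    ``method='moments'`` (default) matches the sample mean and variance;
    ``method='mle'`` maximum-likelihood fits the positive r values.  With
    fewer than 3 values no fit is attempted.  An all-zero sample (every
    calibration binding) is returned flagged degenerate.
    """
    if isinstance(r_values, Mapping):
        vals = np.asarray(list(r_values.values()), dtype=float)
    else:
        vals = np.asarray(list(r_values), dtype=float)
    if family != "lognormal":
        raise ValueError(f"unsupported family {family!r}")
    if len(vals) < 3:
        raise ValueError(
            f"need at least 3 relative ghost times to fit, got {len(vals)}; "
            "add fossil calibrations"
        )
    if np.any(vals < 0):
        raise ValueError("relative ghost times must be non-negative")
    mean_r = float(vals.mean())
    var_r = float(vals.var(ddof=1))
    if mean_r == 0.0:
        return GhostLineageModel(
            family, 0.0, 0.0, None, None, q, len(vals), degenerate=True
        )
    if var_r == 0.0:
        return GhostLineageModel(
            family, mean_r, 0.0, math.log(mean_r), 0.0, q, len(vals)
        )
    if method == "moments":
        meanlog, sdlog = _lognormal_moment_match(mean_r, var_r)
    elif method == "mle":
        pos = vals[vals > 0]
        sdlog, _, scale = stats.lognorm.fit(pos, floc=0)
        meanlog = math.log(scale)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return GhostLineageModel(family, mean_r, var_r, meanlog, sdlog, q, len(vals))


def build_prior(point: CalibrationPoint, model: GhostLineageModel) -> CalibrationDensity:
    """Per-node calibration density from the fitted ghost-lineage model.

    The prior on Td has the shape of FAD*(1+r), offset so its support
    starts at FAD_min: the excess G = Td - FAD_min = (FAD - FAD_min) + FAD*r
    is moment-matched to a lognormal.  The stratigraphic gap FAD - FAD_min
    thus fattens the lower tail without moving the hard floor.  The soft
    maximum is the prior's quantile q.
    """
    if model.degenerate:
        raise ValueError(
            f"{point.node_id}: ghost-lineage model is degenerate (all r = 0); "
            "a point-mass prior at the FAD would leave no room above the "
            "fossil — add calibrations with non-binding FADs"
        )
    gap = point.fad - point.fad_min
    mean_g = gap + point.fad * model.mean_r
    var_g = point.fad**2 * model.var_r
    if var_g == 0.0:
        meanlog, sdlog = math.log(mean_g), 0.0
    else:
        meanlog, sdlog = _lognormal_moment_match(mean_g, var_g)
    dens = CalibrationDensity(
        node_id=point.node_id,
        hard_min=point.fad_min,
        soft_max=0.0,
        offset=point.fad_min,
        meanlog=meanlog,
        sdlog=sdlog,
        q=model.q,
    )
    dens.soft_max = dens.quantile(model.q)
    assert dens.soft_max > dens.hard_min
    return dens


def polymorphism_correction(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, np.ndarray]:
    """OLS of concatenation node ages y on relative species divergence x.

    Alleles coalesce before populations split, so gene-tree node ages
    exceed species divergence times by roughly a constant; the fitted
    intercept a (in the units of y, My) is that interval and ``y - a``
    are the corrected ages.  Returns (a, b, corrected_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired node ages")
    if np.ptp(x) == 0:
        raise ValueError("relative divergence times are constant; slope undefined")
    b, a = np.polyfit(x, y, 1)
    return float(a), float(b), y - a


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_calibration_table(path: str | os.PathLike) -> list[CalibrationPoint]:
    """CSV with header node_id,FAD,FAD_min (case-insensitive), My units."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("node_id", "fad", "fad_min") if c not in df.columns]
    if missing:
        raise ValueError(f"calibration table missing columns {missing}")
    return [
        CalibrationPoint(str(r.node_id), float(r.fad), float(r.fad_min))
        for r in df.itertuples()
    ]


def write_densities(
    densities: Sequence[CalibrationDensity], path: str | os.PathLike
) -> None:
    rows = [
        {
            "node_id": d.node_id,
            "hard_min": d.hard_min,
            "soft_max": d.soft_max,
            "offset": d.offset,
            "meanlog": d.meanlog,
            "sdlog": d.sdlog,
            "q": d.q,
        }
        for d in densities
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
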