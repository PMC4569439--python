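"""Spatial diversity and proximity features of a four-mark point pattern.

Implements the 27 per-patient features: neighbor-abundance indices built on
the closed r-ball neighbor relation (mingling, local Shannon/Simpson, mean
composite information, ISAR), the global mark-abundance Shannon and
Gini-Simpson indices, and the marked second-order / nearest-neighbor
summary functions G_uv, F_v, J_uv = (1-G_uv)/(1-F_v) and K_uv, plus an
intensity-reweighted (inhomogeneous) empty-space function. Every
distance-dependent quantity is evaluated on a radius grid and summarized
by its mean and sample standard deviation over r.

Estimators are the uncorrected empirical versions (no edge correction),
which makes every quantity exactly reproducible by brute-force double
loops; under complete spatial randomness with independent marks they obey
the usual benchmarks (K_uv ~ pi r^2, G/F ~ 1 - exp(-lambda pi r^2),
J ~ 1) away from the window edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.special import gammaln

from .spatial_map import MARKS, MultitypePointPattern

#: the 27 feature names, in canonical order
FEATURE_NAMES = (
    "ISAR", "Mean ISAR", "std-dev ISAR",
    "Mean mingling", "std-dev mingling",
    "Shannon index", "Mean Shannon index", "std-dev Shannon index",
    "Mean MCI", "std-dev MCI",
    "Simpson index", "Mean Simpson index", "std-dev Simpson index",
    "Mean K for T1 and T2", "std-dev K for T1 and T2",
    "Mean K", "std-dev K",
    "Mean J for T1 and T2", "std-dev J for T1 and T2",
    "Mean J", "std-dev J",
    "Mean G for T1 and T2", "std-dev G for T1 and T2",
    "Mean G", "std-dev G",
    "Mean F inhomogeneous", "std-dev F inhomogeneous",
)


@dataclass(frozen=True)
class RGrid:
    """Strictly increasing positive radii (pixel units)."""

    radii: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        if r.ndim != 1 or r.size < 1 or r[0] <= 0 or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly increasing and positive")
        object.__setattr__(self, "radii", r)

    def __len__(self):
        return len(self.radii)


def default_rgrid(pattern: MultitypePointPattern, n: int = 50) -> RGrid:
    """50 radii from w/100 to w/4 where w is the shorter window side."""
    w = min(pattern.window_sides)
    return RGrid(np.linspace(w / 100.0, w / 4.0, n))


@dataclass
class SummaryCurve:
    radii: np.ndarray
    values: np.ndarray          # NaN where undefined
    kind: str
    marks_involved: tuple = ()

    @property
    def is_missing(self) -> bool:
        return bool(np.all(np.isnan(self.values)))


@dataclass
class NeighborCounts:
    """Per-point neighbor abundances at one radius.

    ``delta`` counts all neighbors, ``delta_by_mark`` (n, 4; column order
    follows MARKS) counts per-mark neighbors, ``delta_same`` counts
    neighbors sharing the focal point's mark.
    """

    delta: np.ndarray
    delta_by_mark: np.ndarray
    delta_same: np.ndarray


def _missing_curve(rgrid: RGrid, kind: str, marks=()) -> SummaryCurve:
    return SummaryCurve(rgrid.radii, np.full(len(rgrid), np.nan), kind, marks)


def _pairwise(pattern) -> np.ndarray:
    return cdist(pattern.points, pattern.points)


def _mark_matrix(pattern) -> np.ndarray:
    """Boolean (n, 4) membership matrix in MARKS order."""
    return np.stack([pattern.marks == m for m in MARKS], axis=1)


# ---------------------------------------------------------------------------
# Neighbor-abundance indices (closed r-ball relation: 0 < d <= r)

def neighbor_counts(pattern: MultitypePointPattern, r: float,
                    _dist: np.ndarray | None = None) -> NeighborCounts:
    if r <= 0:
        raise ValueError("r must be > 0")
    D = _pairwise(pattern) if _dist is None else _dist
    adj = (D > 0) & (D <= r)
    member = _mark_matrix(pattern)
    by_mark = adj.astype(np.int64) @ member.astype(np.int64)  # (n, 4) counts
    delta = by_mark.sum(axis=1)
    if len(D):
        same = by_mark[np.arange(len(D)),
                       member.astype(np.int8).argmax(axis=1)]
    else:
        same = np.empty(0)
    return NeighborCounts(delta=delta.astype(int),
                          delta_by_mark=by_mark.astype(int),
                          delta_same=same.astype(int))


def _abundance_curve(pattern, rgrid, per_point_stat) -> np.ndarray:
    """Mean over points with delta > 0 of a per-point neighborhood statistic."""
    D = _pairwise(pattern)
    out = np.full(len(rgrid), np.nan)
    for k, r in enumerate(rgrid.radii):
        nc = neighbor_counts(pattern, r, _dist=D)
        has = nc.delta > 0
        if has.any():
            out[k] = float(np.mean(per_point_stat(nc)[has]))
    return out


def mingling_curve(pattern, rgrid: RGrid) -> SummaryCurve:
    """Mean fraction of a point's r-neighbors carrying a different mark."""
    def stat(nc):
        with np.errstate(invalid="ignore", divide="ignore"):
            return (nc.delta - nc.delta_same) / nc.delta
    return SummaryCurve(rgrid.radii, _abundance_curve(pattern, rgrid, stat),
                        "mingling")


def _entropy_stats(nc):
    with np.errstate(invalid="ignore", divide="ignore"):
        p = nc.delta_by_mark / nc.delta[:, None]
    logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    shannon = -(np.where(p > 0, p, 0.0) * logp).sum(axis=1)
    simpson = 1.0 - np.where(p > 0, p, 0.0).__pow__(2).sum(axis=1)
    return shannon, simpson


def local_shannon_curve(pattern, rgrid: RGrid) -> SummaryCurve:
    vals = _abundance_curve(pattern, rgrid, lambda nc: _entropy_stats(nc)[0])
    return SummaryCurve(rgrid.radii, vals, "shannon")


def local_simpson_curve(pattern, rgrid: RGrid) -> SummaryCurve:
    vals = _abundance_curve(pattern, rgrid, lambda nc: _entropy_stats(nc)[1])
    return SummaryCurve(rgrid.radii, vals, "simpson")


def global_shannon(pattern) -> float:
    """Shannon entropy of the whole-pattern mark proportions."""
    counts = np.array([v for v in pattern.mark_counts().values()], dtype=float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def global_simpson(pattern) -> float:
    """Gini-Simpson index 1 - sum(p^2) of the whole-pattern mark proportions."""
    counts = np.array([v for v in pattern.mark_counts().values()], dtype=float)
    p = counts / counts.sum()
    return float(1.0 - (p**2).sum())


def isar_curve(pattern, rgrid: RGrid) -> SummaryCurve:
    """Individual species-area relationship, averaged over focal marks.

    For focal mark u, the expected number of other marks with at least one
    point within distance r of a typical u-point; d(x, y) <= r (closed,
    zero included).
    """
    present = [m for m, c in pattern.mark_counts().items() if c > 0]
    vals = np.zeros(len(rgrid))
    if len(present) < 2:
        return SummaryCurve(rgrid.radii, vals, "ISAR")
    per_u = []
    for u in present:
        xu = pattern.points_of(u)
        acc = np.zeros(len(rgrid))
        for v in present:
            if v == u:
                continue
            dmin = cdist(xu, pattern.points_of(v)).min(axis=1)
            acc += np.array([(dmin <= r).mean() for r in rgrid.radii])
        per_u.append(acc)
    return SummaryCurve(rgrid.radii, np.mean(per_u, axis=0), "ISAR")


def mci_curve(pattern, rgrid: RGrid) -> SummaryCurve:
    """Mean composite information of neighborhood composition.

    Per point with delta > 0, CI = -(1/delta) * log multinomial pmf of the
    neighborhood mark counts under the whole-pattern mark proportions;
    the curve is the mean of CI over those points.
    """
    counts = np.array([v for v in pattern.mark_counts().values()], dtype=float)
    p = counts / counts.sum()
    logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)

    def stat(nc):
        k = nc.delta_by_mark.astype(float)
        logpmf = (gammaln(nc.delta + 1.0) - gammaln(k + 1.0).sum(axis=1)
                  + (k * logp).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nc.delta > 0, -logpmf / nc.delta, np.nan)

    return SummaryCurve(rgrid.radii, _abundance_curve(pattern, rgrid, stat),
                        "MCI")


# ---------------------------------------------------------------------------
# Marked summary functions (uncorrected estimators)

def _boundary_distance(points, window) -> np.ndarray:
    xmin, xmax, ymin, ymax = window
    return np.minimum.reduce([points[:, 0] - xmin, xmax - points[:, 0],
                              points[:, 1] - ymin, ymax - points[:, 1]])


def marked_G(pattern, u: str, v: str, rgrid: RGrid,
             correction: str = "none") -> SummaryCurve:
    """Empirical CDF over u-points of the nearest type-v neighbor distance.

    ``correction="border"`` uses the reduced-sample estimator (only focal
    points at least r from the window boundary contribute at radius r),
    which is unbiased under complete spatial randomness; the default is
    the plain uncorrected CDF.
    """
    if correction not in ("none", "border"):
        raise ValueError("correction must be 'none' or 'border'")
    xu, xv = pattern.points_of(u), pattern.points_of(v)
    need_v = 2 if u == v else 1
    if len(xu) < 1 or len(xv) < need_v:
        return _missing_curve(rgrid, "G", (u, v))
    D = cdist(xu, xv)
    if u == v:
        np.fill_diagonal(D, np.inf)
    dmin = D.min(axis=1)
    if correction == "border":
        bd = _boundary_distance(xu, pattern.window)
        vals = np.array([(dmin[bd >= r] <= r).mean() if (bd >= r).any()
                         else np.nan for r in rgrid.radii])
    else:
        vals = np.array([(dmin <= r).mean() for r in rgrid.radii])
    return SummaryCurve(rgrid.radii, vals, "G", (u, v))


def _test_lattice(window, n_test: int) -> np.ndarray:
    xmin, xmax, ymin, ymax = window
    k = max(1, int(round(math.sqrt(n_test))))
    xs = xmin + (np.arange(k) + 0.5) * (xmax - xmin) / k
    ys = ymin + (np.arange(k) + 0.5) * (ymax - ymin) / k
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def empty_space_F(pattern, v: str, rgrid: RGrid, n_test: int = 1024,
                  correction: str = "none") -> SummaryCurve:
    """Spherical contact CDF of type v from a regular lattice of test points.

    ``correction="border"`` restricts, at each radius r, to test locations
    at least r from the window boundary (reduced-sample estimator).
    """
    if correction not in ("none", "border"):
        raise ValueError("correction must be 'none' or 'border'")
    xv = pattern.points_of(v)
    if len(xv) < 1:
        return _missing_curve(rgrid, "F", (v,))
    test = _test_lattice(pattern.window, n_test)
    d, _ = cKDTree(xv).query(test)
    if correction == "border":
        bd = _boundary_distance(test, pattern.window)
        vals = np.array([(d[bd >= r] <= r).mean() if (bd >= r).any()
                         else np.nan for r in rgrid.radii])
    else:
        vals = np.array([(d <= r).mean() for r in rgrid.radii])
    return SummaryCurve(rgrid.radii, vals, "F", (v,))


def inhomogeneous_F(pattern, rgrid: RGrid, bandwidth: float = 16.0,
                    n_test: int = 1024) -> SummaryCurve:
    """Empty-space CDF of the pooled pattern, reweighted for inhomogeneity.

    Each test location's contribution is weighted by the reciprocal of a
    Gaussian-kernel intensity estimate at its nearest point; weights are
    normalized so the curve stays in [0, 1]. For a homogeneous pattern the
    weights are near-constant and the curve matches the plain empty-space
    function.
    """
    pts = pattern.points
    if len(pts) < 1:
        return _missing_curve(rgrid, "F_inhom")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    D = cdist(pts, pts)
    lam = np.exp(-0.5 * (D / bandwidth) ** 2).sum(axis=1) \
        / (2.0 * math.pi * bandwidth**2)
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        return _missing_curve(rgrid, "F_inhom")
    test = _test_lattice(pattern.window, n_test)
    d, idx = cKDTree(pts).query(test)
    w = 1.0 / lam[idx]
    w_sum = w.sum()
    vals = np.array([(w * (d <= r)).sum() / w_sum for r in rgrid.radii])
    return SummaryCurve(rgrid.radii, vals, "F_inhom")


def marked_K(pattern, u: str, v: str, rgrid: RGrid,
             correction: str = "none") -> SummaryCurve:
    """Marked K: scaled count of (u, v) pairs within distance r.

    The default is the uncorrected estimator |W|/(n_u n_v) * pair count,
    exactly reproducible by a double loop. ``correction="translation"``
    weights each pair by the reciprocal overlap area of the window with
    its translate (unbiased under CSR; provided for sensitivity analysis).
    """
    if correction not in ("none", "translation"):
        raise ValueError("correction must be 'none' or 'translation'")
    xu, xv = pattern.points_of(u), pattern.points_of(v)
    if len(xu) < 1 or len(xv) < 1 or (u == v and len(xu) < 2):
        return _missing_curve(rgrid, "K", (u, v))
    D = cdist(xu, xv)
    if u == v:
        np.fill_diagonal(D, np.inf)
    area = pattern.window_area
    if correction == "translation":
        w, h = pattern.window_sides
        dx = np.abs(xu[:, None, 0] - xv[None, :, 0])
        dy = np.abs(xu[:, None, 1] - xv[None, :, 1])
        with np.errstate(divide="ignore"):
            wts = area / ((w - dx) * (h - dy))
        scale = area / (len(xu) * len(xv))
        vals = np.array([scale * wts[D <= r].sum() for r in rgrid.radii])
    else:
        scale = area / (len(xu) * len(xv))
        vals = np.array([scale * (D <= r).sum() for r in rgrid.radii])
    return SummaryCurve(rgrid.radii, vals, "K", (u, v))


def marked_J(pattern, u: str, v: str, rgrid: RGrid,
             n_test: int = 1024) -> SummaryCurve:
    """J_uv = (1 - G_uv)/(1 - F_v); undefined where F_v reaches 1."""
    g = marked_G(pattern, u, v, rgrid)
    f = empty_space_F(pattern, v, rgrid, n_test=n_test)
    if g.is_missing or f.is_missing:
        return _missing_curve(rgrid, "J", (u, v))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(f.values < 1.0 - 1e-9,
                        (1.0 - g.values) / (1.0 - f.values), np.nan)
    return SummaryCurve(rgrid.radii, vals, "J", (u, v))


def summarize_curve(curve: SummaryCurve) -> tuple[float, float]:
    """Mean and sample sd over defined radii; missing if fewer than 2."""
    vals = curve.values[np.isfinite(curve.values)]
    if vals.size < 2:
        return (float("nan"), float("nan"))
    return (float(vals.mean()), float(vals.std(ddof=1)))


# ---------------------------------------------------------------------------
# Assembly of the 27-feature vector

@dataclass
class FeatureVector:
    values: pd.Series            # exactly the 27 FEATURE_NAMES
    diagnostics: dict = field(default_factory=dict)


def _pair_mean(curves: list[SummaryCurve], rgrid, kind) -> SummaryCurve:
    if not curves:
        return _missing_curve(rgrid, kind)
    stack = np.stack([c.values for c in curves])
    with np.errstate(invalid="ignore"):
        vals = np.where(np.all(np.isnan(stack), axis=0), np.nan,
                        np.nanmean(stack, axis=0))
    return SummaryCurve(rgrid.radii, vals, kind)


def _ordered_pair_curve(pattern, fn, marks, rgrid, kind) -> SummaryCurve:
    curves = []
    for u in marks:
        for v in marks:
            if u == v:
                continue
            c = fn(pattern, u, v, rgrid)
            if not c.is_missing:
                curves.append(c)
    return _pair_mean(curves, rgrid, kind)


def _modality_curve(pattern, fn, rgrid, kind) -> SummaryCurve:
    """Average the T1 (low/high) and T2 (low/high) pair curves pointwise."""
    per_mod = []
    for marks in (("T1low", "T1high"), ("T2low", "T2high")):
        c = _ordered_pair_curve(pattern, fn, marks, rgrid, kind)
        if not c.is_missing:
            per_mod.append(c)
    return _pair_mean(per_mod, rgrid, kind)


def extract_features(pattern: MultitypePointPattern,
                     rgrid: RGrid | None = None,
                     n_test: int = 1024,
                     bandwidth: float | None = None) -> FeatureVector:
    """Compute all 27 spatial features of one patient's point pattern.

    Degenerate patterns yield missing (NaN) entries rather than silently
    dropped or zero-filled features; the diagnostics dict records which
    feature groups were missing and why.
    """
    diagnostics: dict = {"n_points": pattern.n_points,
                         "mark_counts": pattern.mark_counts()}
    out = pd.Series(np.nan, index=list(FEATURE_NAMES), dtype=float)

    if pattern.n_points < 2:
        diagnostics["missing"] = ["all: fewer than 2 points"]
        return FeatureVector(out, diagnostics)

    rgrid = rgrid or default_rgrid(pattern)
    if bandwidth is None:
        box = pattern.metadata.get("grid", {}).get("box_size", 8)
        bandwidth = 2.0 * box

    isar = isar_curve(pattern, rgrid)
    out["ISAR"] = isar.values[-1]
    out["Mean ISAR"], out["std-dev ISAR"] = summarize_curve(isar)
    out["Mean mingling"], out["std-dev mingling"] = summarize_curve(
        mingling_curve(pattern, rgrid))
    out["Shannon index"] = global_shannon(pattern)
    out["Mean Shannon index"], out["std-dev Shannon index"] = summarize_curve(
        local_shannon_curve(pattern, rgrid))
    out["Mean MCI"], out["std-dev MCI"] = summarize_curve(
        mci_curve(pattern, rgrid))
    out["Simpson index"] = global_simpson(pattern)
    out["Mean Simpson index"], out["std-dev Simpson index"] = summarize_curve(
        local_simpson_curve(pattern, rgrid))

    j_fn = lambda p, u, v, rg: marked_J(p, u, v, rg, n_test=n_test)
    for label, fn in (("K", marked_K), ("J", j_fn), ("G", marked_G)):
        mod = _modality_curve(pattern, fn, rgrid, label)
        full = _ordered_pair_curve(pattern, fn, MARKS, rgrid, label)
        (out[f"Mean {label} for T1 and T2"],
         out[f"std-dev {label} for T1 and T2"]) = summarize_curve(mod)
        out[f"Mean {label}"], out[f"std-dev {label}"] = summarize_curve(full)

    fin = inhomogeneous_F(pattern, rgrid, bandwidth=bandwidth, n_test=n_test)
    out["Mean F inhomogeneous"], out["std-dev F inhomogeneous"] = \
        summarize_curve(fin)

    missing = [name for name in FEATURE_NAMES if not np.isfinite(out[name])]
    if missing:
        diagnostics["missing"] = missing
    return FeatureVector(out, diagnostics)
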