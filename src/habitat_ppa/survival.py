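"""Survival screening of spatial features.

Each feature is dichotomized at a cutoff and the induced groups compared
by Kaplan-Meier / log-rank, with Benjamini-Hochberg control of the false
discovery rate across features. The default cutoff is the ROC-optimal
(Youden) threshold against the 12-month survival class; a data-independent
median split is also available — the optimized cutoff is anti-conservative
for the subsequent log-rank test (maximally selected cutpoints), so the
median split is the one with calibrated type-I error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests


@dataclass
class ROCResult:
    thresholds: np.ndarray   # decreasing; first entry is +inf
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class DichotomyResult:
    feature_name: str
    cutoff: float
    n_below: int
    n_above: int
    logrank_stat: float
    p_value: float
    p_adjusted: float = float("nan")
    n_used: int = 0


def roc_curve(scores, labels) -> ROCResult:
    """Full ROC sweep over all distinct thresholds; AUC by trapezoid."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr,
                     auc=float(_trapezoid_auc(fpr, tpr)))


def optimal_cutoff(roc: ROCResult) -> float:
    """Threshold maximizing sensitivity + specificity (Youden).

    Ties resolve toward the smallest threshold value; the sentinel +inf
    threshold is never returned unless it is the only one.
    """
    youden = roc.tpr - roc.fpr
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise ValueError("ROC has no finite thresholds")
    thr, y = roc.thresholds[finite], youden[finite]
    if np.allclose(y, y[0]):
        if len(thr) == 1:
            warnings.warn("degenerate ROC (constant scores); returning the "
                          "single threshold")
        # all thresholds equivalent: smallest
        return float(thr.min())
    best = y.max()
    return float(thr[np.isclose(y, best)].min())


def dichotomize(scores, cutoff: float) -> np.ndarray:
    """Group indicator: 1 for scores at or above the cutoff, else 0."""
    return (np.asarray(scores, dtype=float) >= cutoff).astype(int)


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) with hypergeometric variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    group = np.asarray(group).astype(int)
    g0, g1 = group == 0, group == 1
    if not g0.any() or not g1.any():
        raise ValueError("both groups must be nonempty")
    if events.sum() == 0:
        return (0.0, 1.0)
    res = _lifelines_logrank(times[g0], times[g1],
                             event_observed_A=events[g0],
                             event_observed_B=events[g1])
    return (float(res.test_statistic), float(res.p_value))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def kaplan_meier(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate as (event_times, survival)."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=np.asarray(events).astype(int))
    sf = kmf.survival_function_
    return (sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float))


def pooled_mean(group_means, group_ns) -> float:
    """Count-weighted grand mean of group means."""
    m = np.asarray(group_means, dtype=float)
    n = np.asarray(group_ns, dtype=float)
    if m.shape != n.shape:
        raise ValueError("group_means and group_ns must have equal length")
    return float((m * n).sum() / n.sum())


def pooled_sd(group_means, group_sds, group_ns) -> float:
    """Pooled sd via total sum-of-squares decomposition, denominator N-1."""
    m = np.asarray(group_means, dtype=float)
    s = np.asarray(group_sds, dtype=float)
    n = np.asarray(group_ns, dtype=float)
    if not (m.shape == s.shape == n.shape):
        raise ValueError("inputs must have equal length")
    if np.any(n < 2):
        raise ValueError("each group needs n >= 2")
    grand = pooled_mean(m, n)
    ss = ((n - 1) * s**2).sum() + (n * (m - grand) ** 2).sum()
    return float(np.sqrt(ss / (n.sum() - 1)))


def feature_screen(features: pd.DataFrame, times, events, os_class,
                   positive_class: str = "le12",
                   cutoff_method: str = "roc") -> pd.DataFrame:
    """Per-feature dichotomized log-rank screen with BH-FDR correction.

    ``features`` holds one column per spatial feature (rows = patients,
    aligned with ``times``/``events``/``os_class``). Missing feature values
    are handled complete-case per feature, with the used count reported.
    """
    if cutoff_method not in ("roc", "median"):
        raise ValueError("cutoff_method must be 'roc' or 'median'")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    labels_all = (np.asarray(os_class) == positive_class).astype(int)

    rows: list[DichotomyResult] = []
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        ok = np.isfinite(col)
        res = DichotomyResult(feature_name=name, cutoff=float("nan"),
                              n_below=0, n_above=0,
                              logrank_stat=float("nan"),
                              p_value=float("nan"), n_used=int(ok.sum()))
        try:
            scores = col[ok]
            if cutoff_method == "roc":
                cutoff = optimal_cutoff(roc_curve(scores, labels_all[ok]))
            else:
                cutoff = float(np.median(scores))
            group = dichotomize(scores, cutoff)
            stat, p = logrank_test(times[ok], events[ok], group)
            res.cutoff = cutoff
            res.n_below = int((group == 0).sum())
            res.n_above = int((group == 1).sum())
            res.logrank_stat = stat
            res.p_value = p
        except ValueError:
            pass  # degenerate feature: reported with NaN statistics
        rows.append(res)

    raw = np.array([r.p_value for r in rows])
    ok = np.isfinite(raw)
    if ok.any():
        adj = bh_fdr(raw[ok])
        j = 0
        for i, r in enumerate(rows):
            if ok[i]:
                r.p_adjusted = float(adj[j])
                j += 1

    df = pd.DataFrame([vars(r) for r in rows])
    return df.sort_values("p_value", na_position="last").reset_index(drop=True)


def plot_kaplan_meier(times, events, group, path, labels=("below", "above")):
    """Save a two-group Kaplan-Meier plot (survival vs months) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    group = np.asarray(group).astype(int)
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, label in zip((0, 1), labels):
        t, s = kaplan_meier(np.asarray(times, float)[group == g],
                            np.asarray(events)[group == g])
        ax.step(t, s, where="post", label=f"{label} (n={int((group == g).sum())})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def demographics_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary by 12-month class: sex counts, age and OS mean +/- sd."""
    rows = []
    groups = {"le12": clinical[clinical.os_class == "le12"],
              "gt12": clinical[clinical.os_class == "gt12"],
              "total": clinical}
    for label, g in groups.items():
        rows.append({
            "group": label, "n": len(g),
            "male": int((g.sex == "M").sum()),
            "female": int((g.sex == "F").sum()),
            "age_mean": g.age_years.mean(), "age_sd": g.age_years.std(ddof=1),
            "os_mean": g.os_months.mean(), "os_sd": g.os_months.std(ddof=1),
        })
    return pd.DataFrame(rows)
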