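"""Descriptive summaries and condition comparisons of activity metrics.

Thin conveniences over standard routines: per-metric descriptive statistics
(mean, SD, coefficient of variation sigma/|mu|, quartiles, 5th/95th
percentiles), Welch two-sample t-tests between conditions, and a
standardized PCA over the main activity variables (CTime, ETime, nBurst,
nCP) with explained-variance fractions and loadings. No bespoke statistics
live here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import ActivityMetrics

__all__ = [
    "ConditionSummary",
    "metrics_frame",
    "summarize",
    "compare_conditions",
]

DEFAULT_PCA_VARS = ("ctime", "etime", "n_burst", "n_cp")

SCALAR_METRICS = [
    "ctime", "etime", "n_burst", "n_icbi", "n_cp", "hyai",
    "mean_cpi", "mean_icbi", "mean_burst_time",
]


@dataclass
class ConditionSummary:
    """Descriptive statistics of the scalar metrics for one condition."""

    condition: str
    n_recordings: int
    table: pd.DataFrame  # index: metric; columns: mean, sd, cv, q1, median, q3, p5, p95


def metrics_frame(metrics: Iterable[ActivityMetrics]) -> pd.DataFrame:
    """Tidy per-recording table of scalar metrics (one row per recording)."""
    return pd.DataFrame([m.scalars() for m in metrics])


def summarize(metrics: Sequence[ActivityMetrics], condition: str = "") -> ConditionSummary:
    """Descriptive statistics per metric; cv = sigma/|mu| (NaN when mu = 0)."""
    if len(metrics) == 0:
        raise ValueError("summarize needs at least one recording")
    df = metrics_frame(metrics)
    rows = {}
    for m in SCALAR_METRICS:
        v = df[m].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        mu = v.mean()
        sd = v.std(ddof=1) if v.size > 1 else 0.0
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        p5, p95 = np.percentile(v, [5, 95])
        rows[m] = {
            "mean": mu,
            "sd": sd,
            "cv": sd / abs(mu) if mu != 0 else np.nan,
            "q1": q1,
            "median": med,
            "q3": q3,
            "p5": p5,
            "p95": p95,
        }
    return ConditionSummary(condition=condition, n_recordings=len(metrics),
                            table=pd.DataFrame(rows).T)


def compare_conditions(
    a: Sequence[ActivityMetrics],
    b: Sequence[ActivityMetrics],
    label_a: str = "A",
    label_b: str = "B",
    pca_vars: Sequence[str] = DEFAULT_PCA_VARS,
    equal_var: bool = False,
    standardize: bool = True,
    plots_dir: str | os.PathLike | None = None,
) -> dict:
    """Per-metric two-sample t-tests plus a PCA over the main variables.

    The t-test defaults to the Welch (unequal-variance) form. PCA rows are
    recordings from both conditions pooled; variables are standardized to
    unit variance by default. Set ``plots_dir`` to also export box plots and
    a PCA biplot.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both conditions need at least one recording")
    fa, fb = metrics_frame(a), metrics_frame(b)
    report: dict = {
        "conditions": [label_a, label_b],
        "n": {label_a: len(a), label_b: len(b)},
        "summaries": {
            label_a: summarize(a, label_a).table.to_dict(orient="index"),
            label_b: summarize(b, label_b).table.to_dict(orient="index"),
        },
        "t_tests": {},
    }
    for m in SCALAR_METRICS:
        va = fa[m].to_numpy(dtype=float)
        vb = fb[m].to_numpy(dtype=float)
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        if va.size < 2 or vb.size < 2:
            report["t_tests"][m] = {"skipped": "group size < 2"}
            continue
        t, p = sps.ttest_ind(va, vb, equal_var=equal_var)
        report["t_tests"][m] = {"t": float(t), "p": float(p),
                                "significant_0.05": bool(p <= 0.05)}

    X = pd.concat([fa[list(pca_vars)], fb[list(pca_vars)]], ignore_index=True)
    X = X.dropna()
    if len(X) > len(pca_vars):
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler

        M = X.to_numpy(dtype=float)
        if standardize:
            M = StandardScaler().fit_transform(M)
        else:
            M = M - M.mean(axis=0)
        pca = PCA()
        scores = pca.fit_transform(M)
        report["pca"] = {
            "variables": list(pca_vars),
            "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
            "loadings": pca.components_.tolist(),
        }
    else:
        scores = None
        report["pca"] = {"skipped": "too few recordings for PCA"}

    if plots_dir is not None:
        _export_plots(fa, fb, label_a, label_b, scores, pca_vars, report, plots_dir)
    return report


def _export_plots(fa, fb, label_a, label_b, scores, pca_vars, report, plots_dir):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(plots_dir, exist_ok=True)
    metrics = [m for m in SCALAR_METRICS if m in fa.columns]
    fig, axes = plt.subplots(3, 3, figsize=(10, 8))
    for ax, m in zip(axes.ravel(), metrics):
        va = fa[m].replace([np.inf, -np.inf], np.nan).dropna()
        vb = fb[m].replace([np.inf, -np.inf], np.nan).dropna()
        ax.boxplot([va, vb], tick_labels=[label_a, label_b], whis=(5, 95),
                   showmeans=True)
        ax.set_title(m, fontsize=8)
    fig.tight_layout()
    fig.savefig(os.path.join(plots_dir, "boxplots.png"), dpi=150)
    plt.close(fig)

    if scores is not None:
        n_a = len(fa[list(pca_vars)].dropna())
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(scores[:n_a, 0], scores[:n_a, 1], label=label_a)
        ax.scatter(scores[n_a:, 0], scores[n_a:, 1], label=label_b, marker="s")
        load = np.asarray(report["pca"]["loadings"])
        scale = np.abs(scores[:, :2]).max() * 0.9
        for j, name in enumerate(pca_vars):
            ax.annotate(name, (load[0, j] * scale, load[1, j] * scale), color="red")
            ax.arrow(0, 0, load[0, j] * scale, load[1, j] * scale,
                     color="red", alpha=0.4)
        evr = report["pca"]["explained_variance_ratio"]
        ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(os.path.join(plots_dir, "pca_biplot.png"), dpi=150)
        plt.close(fig)
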