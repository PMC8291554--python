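"""Region-level activation statistics for whole-brain c-Fos counting.

Works on a long-format activation table — one row per (animal, region) with
the activated-cell count and a group label ("FST" vs "control") — and
computes the cohort statistics used to compare a stressed group against
controls across 14 subcortical regions:

* relative z-score: z_i = (x_i − x̄_ctrl) / SD_ctrl, per region, for every
  animal including the controls themselves;
* coefficient of variation SD/mean per region per group;
* Welch two-sample t-tests with Benjamini–Hochberg FDR q-values across
  regions, plus fold change mean_FST/mean_ctrl.

Sample standard deviations use ddof=1 throughout.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "validate_table",
    "relative_zscore",
    "coefficient_of_variation",
    "bh_qvalues",
    "storey_qvalues",
    "group_test",
    "cohort_report",
]

REQUIRED_COLUMNS = ("animal_id", "group", "region", "count")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"activation table missing columns {missing}")
    if (table["count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    return table


def _wide(table: pd.DataFrame) -> pd.DataFrame:
    return table.pivot_table(index=["animal_id", "group"], columns="region",
                             values="count", aggfunc="first")


def relative_zscore(table: pd.DataFrame, control_group: str = "control") -> pd.DataFrame:
    """Per-animal, per-region z relative to the control distribution.

    Regions where the control SD is zero are returned as NaN (undefined).
    By construction, the control animals' z-scores in each region have
    sample mean 0 and sample SD 1.
    """
    validate_table(table)
    wide = _wide(table)
    ctrl = wide.xs(control_group, level="group")
    if len(ctrl) < 2:
        raise ValueError("need >= 2 control animals")
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    z = (wide - mu) / sd.replace(0.0, np.nan)
    return z


def coefficient_of_variation(table: pd.DataFrame, group: str) -> pd.Series:
    """CV = SD/mean per region for one group; NaN where the mean is zero."""
    validate_table(table)
    wide = _wide(table)
    sub = wide.xs(group, level="group")
    mean = sub.mean(axis=0)
    cv = sub.std(axis=0, ddof=1) / mean.replace(0.0, np.nan)
    return cv


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j)·m/j."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalues(pvalues: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with fixed λ: π0 = #{p > λ}/(m(1−λ)), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    pi0 = min(np.mean(p > lam) / (1.0 - lam), 1.0)
    if pi0 == 0.0:
        pi0 = 1.0 / m
    return np.minimum(pi0 * bh_qvalues(p), 1.0)


def _permutation_p(a: np.ndarray, b: np.ndarray, max_exact: int = 20000) -> float:
    """Exact (or near-exact) two-sided permutation p for the mean difference."""
    pooled = np.concatenate([a, b])
    n = len(a)
    obs = abs(a.mean() - b.mean())
    idx = range(len(pooled))
    combos = itertools.combinations(idx, n)
    total = math.comb(len(pooled), n)
    if total > max_exact:
        rng = np.random.default_rng(0)
        count = hits = 0
        for _ in range(max_exact):
            sel = rng.permutation(len(pooled))[:n]
            mask = np.zeros(len(pooled), bool)
            mask[sel] = True
            d = abs(pooled[mask].mean() - pooled[~mask].mean())
            hits += d >= obs - 1e-12
            count += 1
        return (hits + 1) / (count + 1)
    hits = 0
    for sel in combos:
        mask = np.zeros(len(pooled), bool)
        mask[list(sel)] = True
        d = abs(pooled[mask].mean() - pooled[~mask].mean())
        hits += d >= obs - 1e-12
    return hits / total


def group_test(
    table: pd.DataFrame,
    group_a: str = "FST",
    group_b: str = "control",
    fdr: str = "bh",
) -> pd.DataFrame:
    """Per-region Welch t-test with FDR correction across regions.

    Returns a DataFrame indexed by region with t, p, q, fold change
    (mean_a/mean_b) and both groups' CVs.  Regions with zero variance in
    both groups fall back to an exact permutation p-value.
    """
    validate_table(table)
    wide = _wide(table)
    a = wide.xs(group_a, level="group")
    b = wide.xs(group_b, level="group")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 animals")
    rows = {}
    for region in wide.columns:
        xa, xb = a[region].to_numpy(float), b[region].to_numpy(float)
        if xa.std(ddof=1) == 0.0 and xb.std(ddof=1) == 0.0:
            if xa.mean() == xb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = np.inf, _permutation_p(xa, xb)
        else:
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
        mb = xb.mean()
        rows[region] = dict(
            t=float(t), p=float(p),
            fold_change=float(xa.mean() / mb) if mb > 0 else np.nan,
            cv_a=float(xa.std(ddof=1) / xa.mean()) if xa.mean() > 0 else np.nan,
            cv_b=float(xb.std(ddof=1) / mb) if mb > 0 else np.nan,
        )
    res = pd.DataFrame(rows).T
    qfun = {"bh": bh_qvalues, "storey": storey_qvalues}[fdr]
    res["q"] = qfun(res["p"].to_numpy())
    res.index.name = "region"
    return res[["t", "p", "q", "fold_change", "cv_a", "cv_b"]]


def cohort_report(
    table: pd.DataFrame,
    group_a: str = "FST",
    group_b: str = "control",
    fdr: str = "bh",
    plot_path: str | None = None,
) -> dict:
    """Full cohort summary: test table, z-score matrix, CV pairs.

    Returns a dict with ``stats`` (per-region test results), ``zscores``
    (animals × regions matrix relative to the control group) and ``cv``
    (per-region CV for both groups).  If ``plot_path`` is given, a z-score
    heatmap and CV scatter are written there (requires matplotlib).
    """
    stats = group_test(table, group_a, group_b, fdr=fdr)
    z = relative_zscore(table, control_group=group_b)
    cv = pd.DataFrame({group_a: coefficient_of_variation(table, group_a),
                       group_b: coefficient_of_variation(table, group_b)})
    if plot_path is not None:
        _plot_report(z, cv, group_a, group_b, plot_path)
    return {"stats": stats, "zscores": z, "cv": cv}


def _plot_report(z, cv, group_a, group_b, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4.2))
    im = ax1.imshow(z.to_numpy(float), aspect="auto", cmap="coolwarm",
                    vmin=-4, vmax=4)
    ax1.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=7)
    ax1.set_yticks(range(z.shape[0]), [i[0] for i in z.index], fontsize=7)
    ax1.set_title("relative z-score")
    fig.colorbar(im, ax=ax1)
    lim = float(np.nanmax(cv.to_numpy())) * 1.1
    ax2.scatter(cv[group_b], cv[group_a], s=18)
    ax2.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax2.set_xlabel(f"CV {group_b}")
    ax2.set_ylabel(f"CV {group_a}")
    ax2.set_title("per-region CV")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
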