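"""Clonal conversion-rate analysis.

Each clone observed both at the starting timepoint (D0) and in the
post-induction window contributes one observation: its D0 glial-cluster
composition (a point on the simplex) and the fraction of its post-induction
cells that became neurons.  Regressing conversion fraction on composition
without an intercept yields per-cluster coefficients directly interpretable
as cluster-specific conversion rates; an F-type contrast tests whether all
clusters convert at the same rate.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import kruskal


def build_clone_composition(
    clones: pd.DataFrame,
    clusters: Sequence[str],
    d0_label: str = "D0",
    post_labels: Sequence[str] = ("D2", "D3", "D5", "D7"),
    cluster_col: str = "cluster",
    timepoint_col: str = "timepoint",
    neuron_col: str = "is_neuron",
) -> pd.DataFrame:
    """One row per clone with D0 composition and post-window conversion.

    Clones lacking cells in either window are excluded (and counted in the
    ``n_excluded`` attribute of the returned frame).  Raises ``ValueError``
    when no clone qualifies.
    """
    rows = []
    n_excluded = 0
    post_labels = set(post_labels)
    for cid, grp in clones.groupby("clone_id", sort=True):
        d0 = grp[grp[timepoint_col] == d0_label]
        post = grp[grp[timepoint_col].isin(post_labels)]
        if len(d0) == 0 or len(post) == 0:
            n_excluded += 1
            continue
        comp = d0[cluster_col].value_counts(normalize=True)
        row = {
            "clone_id": cid,
            "n_d0_cells": len(d0),
            "n_post_cells": len(post),
            "conversion_fraction": float(post[neuron_col].astype(bool).mean()),
        }
        for c in clusters:
            row[f"comp_{c}"] = float(comp.get(c, 0.0))
        rows.append(row)
    if not rows:
        raise ValueError("no clone has cells in both the D0 and post windows")
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out


def fit_conversion_model(
    rows: pd.DataFrame, clusters: Sequence[str]
) -> dict:
    """Weighted no-intercept least squares of conversion on D0 composition.

    Weights are the post-window cell counts.  Returns per-cluster
    coefficients (conversion rates) with 95% CIs, and an F-test of the
    global hypothesis that all coefficients are equal.  Clusters never
    observed at D0 get an NA coefficient with a warning.
    """
    comp_cols = [f"comp_{c}" for c in clusters]
    X = rows[comp_cols].to_numpy()
    observed = X.sum(axis=0) > 0
    if not observed.all():
        absent = [c for c, o in zip(clusters, observed) if not o]
        warnings.warn(f"clusters never observed at D0, coefficient NA: {absent}")
    used = [c for c, o in zip(clusters, observed) if o]
    Xu = X[:, observed]
    if len(rows) < len(clusters):
        raise ValueError(
            f"underdetermined: {len(rows)} clones for {len(clusters)} cluster rates"
        )
    y = rows["conversion_fraction"].to_numpy()
    w = rows["n_post_cells"].to_numpy().astype(float)

    model = sm.WLS(y, Xu, weights=w)
    fit = model.fit()
    ci = fit.conf_int(alpha=0.05)

    coef = {c: np.nan for c in clusters}
    ci_lo = {c: np.nan for c in clusters}
    ci_hi = {c: np.nan for c in clusters}
    for i, c in enumerate(used):
        coef[c] = float(fit.params[i])
        ci_lo[c], ci_hi[c] = float(ci[i][0]), float(ci[i][1])

    # global equality: k-1 contrasts b_i - b_0 = 0
    if len(used) >= 2 and len(rows) > len(used):
        R = np.zeros((len(used) - 1, len(used)))
        R[:, 0] = -1.0
        for i in range(1, len(used)):
            R[i - 1, i] = 1.0
        if np.abs(R @ fit.params).max() < 1e-10:
            # coefficients agree exactly (e.g. zero-residual fits); nothing
            # to reject and the F ratio would be 0/0
            f_stat, f_p = 0.0, 1.0
        else:
            ftest = fit.f_test(R)
            f_stat, f_p = float(ftest.fvalue), float(ftest.pvalue)
    else:
        f_stat, f_p = np.nan, np.nan

    return {
        "coefficients": coef,
        "ci_lower": ci_lo,
        "ci_upper": ci_hi,
        "equality_F": f_stat,
        "equality_p": f_p,
        "n_clones": int(len(rows)),
        "residual_df": int(fit.df_resid),
    }


def _box_stats(values: np.ndarray) -> dict:
    # linear-interpolation (type-7) quartiles; "outliers" are clones outside
    # the Q1-Q3 box, matching a box plot that draws only the quartile range
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    outliers = values[(values < q1) | (values > q3)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "n_outliers": int(len(outliers)),
    }


def per_cluster_conversion(
    clones: pd.DataFrame,
    clusters: Sequence[str],
    d0_label: str = "D0",
    post_labels: Sequence[str] = ("D2", "D3", "D5", "D7"),
    mode: str = "pure",
    cluster_col: str = "cluster",
    timepoint_col: str = "timepoint",
    neuron_col: str = "is_neuron",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Distribution over clones of conversion fraction, per starting cluster.

    ``mode='pure'`` attributes only clones whose D0 cells sit in a single
    cluster; ``mode='weighted'`` attributes every clone to each cluster it
    occupies at D0.  Returns the per-(clone, cluster) table, per-cluster box
    statistics (type-7 median/Q1/Q3 with points outside the box counted as
    outliers), and a Kruskal-Wallis test across clusters.
    """
    if mode not in {"pure", "weighted"}:
        raise ValueError("mode must be 'pure' or 'weighted'")
    comp = build_clone_composition(
        clones, clusters, d0_label, post_labels, cluster_col, timepoint_col, neuron_col
    )
    rows = []
    for _, r in comp.iterrows():
        fracs = {c: r[f"comp_{c}"] for c in clusters}
        if mode == "pure":
            top = [c for c, f in fracs.items() if f == 1.0]
            if not top:
                continue
            attributed = top
        else:
            attributed = [c for c, f in fracs.items() if f > 0]
        for c in attributed:
            rows.append(
                {
                    "clone_id": r["clone_id"],
                    "cluster": c,
                    "conversion_fraction": r["conversion_fraction"],
                    "n_post_cells": r["n_post_cells"],
                }
            )
    table = pd.DataFrame(
        rows, columns=["clone_id", "cluster", "conversion_fraction", "n_post_cells"]
    )

    box_rows = []
    groups = []
    for c in clusters:
        vals = table.loc[table["cluster"] == c, "conversion_fraction"].to_numpy()
        if len(vals) == 0:
            warnings.warn(f"cluster {c} has no clone coverage; omitted")
            continue
        stats = _box_stats(vals)
        stats.update({"cluster": c, "n_clones": len(vals)})
        box_rows.append(stats)
        groups.append(vals)
    box = pd.DataFrame(box_rows)

    if len(groups) >= 2:
        try:
            kw = kruskal(*groups)
            kw_out = {"H": float(kw.statistic), "pvalue": float(kw.pvalue)}
        except ValueError:  # all values identical across groups
            kw_out = {"H": 0.0, "pvalue": 1.0}
    else:
        kw_out = {"H": np.nan, "pvalue": np.nan}
    return table, box, kw_out
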