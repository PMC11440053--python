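"""Per-cell transgene detection and the partial- vs all-three-factor analysis.

A cell is positive for a conversion factor when it has at least one UMI for
that transgene.  Cells are grouped as ``none`` (no factor detected),
``partial`` (one or two factors) or ``all_three``; ``any`` denotes the union
of partial and all_three.  The central comparison asks whether cells
co-expressing all three factors convert to neurons more often than cells
with partial expression (Fisher's exact test on the 2x2 contingency).
"""

from __future__ import annotations

import warnings
from typing import Dict, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import fisher_exact, mannwhitneyu

from . import io as ctio


def call_tf_positive(
    adata: ad.AnnData, tf_features: Sequence[str] | None = None
) -> pd.DataFrame:
    """Call per-cell factor positivity (>= 1 UMI) and assign TF groups.

    ``tf_features`` names the transgene features used for the three-factor
    logic; by default every feature of class Transgene is used.  Additional
    cassettes (e.g. shRNA/rtTA) present in the feature table are counted in
    the output but excluded from the group logic when ``tf_features`` is
    given.  Raises ``ValueError`` if a designated feature is missing.
    """
    classes = adata.var.get(
        "feature_class", pd.Series(ctio.GENE_CLASS, index=adata.var_names)
    )
    all_tg = [v for v in adata.var_names if classes[v] == ctio.TRANSGENE_CLASS]
    if tf_features is None:
        tf_features = all_tg
    missing = [f for f in tf_features if f not in adata.var_names]
    if missing:
        raise ValueError(f"designated transgene features missing: {missing}")
    if not tf_features:
        raise ValueError("no transgene features designated or present")

    counts = adata.layers.get("counts", adata.X)
    table = pd.DataFrame(index=adata.obs_names)
    report_features = list(dict.fromkeys(list(tf_features) + all_tg))
    for f in report_features:
        col = counts[:, adata.var_names.get_loc(f)]
        vals = np.asarray(col.todense()).ravel() if sp.issparse(col) else np.ravel(col)
        table[f"umi_{f}"] = vals.astype(int)
        table[f"pos_{f}"] = vals >= 1

    n_pos = table[[f"pos_{f}" for f in tf_features]].sum(axis=1)
    group = pd.Series("none", index=table.index, dtype=object)
    group[n_pos >= 1] = "partial"
    group[n_pos == len(tf_features)] = "all_three"
    table["n_factors"] = n_pos
    table["group"] = group
    table["any_tf"] = n_pos >= 1
    return table


def neuron_fraction_by_group(
    calls: pd.DataFrame, is_neuron: pd.Series
) -> dict:
    """Neuron fraction for all_three vs partial cells, with Fisher's exact p.

    Builds the 2x2 contingency (group x neuron) over the disjoint all_three
    and partial groups and applies the two-sided Fisher exact test.  Raises
    ``ValueError`` when either group is empty.
    """
    neuron = is_neuron.loc[calls.index].astype(bool)
    groups = {}
    for name in ("all_three", "partial"):
        mask = calls["group"] == name
        if mask.sum() == 0:
            raise ValueError(f"group {name!r} is empty")
        groups[name] = (
            int((mask & neuron).sum()),
            int((mask & ~neuron).sum()),
        )
    table = np.array([groups["all_three"], groups["partial"]])
    _, p = fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "fraction_all_three": table[0, 0] / table[0].sum(),
        "fraction_partial": table[1, 0] / table[1].sum(),
        "fisher_p": float(p),
    }


def transgene_level_by_group(
    adata: ad.AnnData,
    calls: pd.DataFrame,
    neuron_cells: Sequence[str],
    tf_features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Normalized transgene expression in neuronal cells, all_three vs partial.

    One row per transgene with group means and the two-sided rank-sum p.
    Returns NA (with a warning) for transgenes where a group is empty in the
    neuronal cluster.
    """
    if tf_features is None:
        classes = adata.var.get(
            "feature_class", pd.Series(ctio.GENE_CLASS, index=adata.var_names)
        )
        tf_features = [v for v in adata.var_names if classes[v] == ctio.TRANSGENE_CLASS]
    neuron_cells = [c for c in neuron_cells if c in calls.index]
    sub_calls = calls.loc[neuron_cells]

    rows = []
    for f in tf_features:
        expr = adata[neuron_cells, f].X
        expr = (
            np.asarray(expr.todense()).ravel() if sp.issparse(expr) else np.ravel(expr)
        )
        x = expr[(sub_calls["group"] == "all_three").to_numpy()]
        y = expr[(sub_calls["group"] == "partial").to_numpy()]
        if len(x) == 0 or len(y) == 0:
            warnings.warn(f"{f}: a group is empty among neuronal cells; p = NA")
            rows.append({"transgene": f, "mean_all_three": np.nan,
                         "mean_partial": np.nan, "pvalue": np.nan})
            continue
        p = mannwhitneyu(x, y, alternative="two-sided").pvalue
        rows.append(
            {
                "transgene": f,
                "mean_all_three": float(np.mean(x)),
                "mean_partial": float(np.mean(y)),
                "pvalue": float(p),
            }
        )
    return pd.DataFrame(rows)


def maturation_by_group(
    scores: pd.Series, calls: pd.DataFrame
) -> Dict[str, dict]:
    """Maturation module score by TF group with the two ordered comparisons.

    Returns per-group summary statistics plus rank-sum p-values for
    none-vs-any and any-vs-all_three (``any`` here being the partial group,
    so the three distributions are disjoint).  A comparison involving an
    absent or single-cell group is NA with a warning.
    """
    scores = scores.loc[calls.index]
    dists = {
        name: scores[(calls["group"] == name).to_numpy()]
        for name in ("none", "partial", "all_three")
    }
    out: Dict[str, dict] = {
        "groups": {
            name: {
                "n": int(len(vals)),
                "median": float(np.median(vals)) if len(vals) else np.nan,
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
            }
            for name, vals in dists.items()
        }
    }
    for label, (ga, gb) in {
        "none_vs_any": ("none", "partial"),
        "any_vs_all_three": ("partial", "all_three"),
    }.items():
        a, b = dists[ga], dists[gb]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"comparison {label}: group too small; p = NA")
            out[label] = {"pvalue": np.nan}
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            out[label] = {"pvalue": 1.0}
            continue
        out[label] = {
            "pvalue": float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        }
    return out
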