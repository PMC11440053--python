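"""Permutation test for differential cluster abundance between two conditions.

For each cluster the statistic is the log2 fold-difference of its proportion
between the two conditions, with 0.5 pseudo-cells added to every
cluster x condition count.  The null distribution comes from shuffling the
condition labels across cells at fixed group sizes; confidence intervals
come from a percentile bootstrap of cells within each condition; multiplicity
is controlled with Benjamini-Hochberg across clusters.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._rng import substream


def _log2_fd(counts_a: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    pa = (counts_a + 0.5) / (counts_a + 0.5).sum()
    pb = (counts_b + 0.5) / (counts_b + 0.5).sum()
    return np.log2(pb / pa)


def permutation_proportion_test(
    cluster_labels: Sequence,
    condition_labels: Sequence,
    condition_a: str | None = None,
    condition_b: str | None = None,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sided permutation test of per-cluster abundance between conditions.

    Returns one row per cluster with counts, the observed log2
    fold-difference (B relative to A), the permutation p-value with the
    add-one correction ``(1 + #{|stat*| >= |stat|}) / (n_perm + 1)``, a 95%
    percentile-bootstrap CI and the BH-adjusted FDR.  Requires exactly two
    condition levels, each with at least 2 cells.
    """
    clusters = pd.Series(list(cluster_labels), name="cluster")
    conditions = pd.Series(list(condition_labels), name="condition")
    if len(clusters) != len(conditions):
        raise ValueError("cluster and condition labels differ in length")

    levels = sorted(conditions.unique())
    if len(levels) != 2:
        raise ValueError(
            f"expected exactly 2 conditions, got {levels}; run pairwise comparisons"
        )
    if condition_a is None or condition_b is None:
        condition_a, condition_b = levels
    for lvl in (condition_a, condition_b):
        if (conditions == lvl).sum() < 2:
            raise ValueError(f"condition {lvl!r} has fewer than 2 cells")

    cluster_names = sorted(clusters.unique())
    onehot = pd.get_dummies(pd.Categorical(clusters, categories=cluster_names))
    C = onehot.to_numpy(dtype=np.float64)  # n_cells x k
    is_b = (conditions == condition_b).to_numpy()

    counts_a = C[~is_b].sum(axis=0)
    counts_b = C[is_b].sum(axis=0)
    both_absent = (counts_a + counts_b) == 0
    if both_absent.any():
        dropped = [c for c, d in zip(cluster_names, both_absent) if d]
        warnings.warn(f"clusters absent in both conditions dropped: {dropped}")
        keep = ~both_absent
        C = C[:, keep]
        counts_a, counts_b = counts_a[keep], counts_b[keep]
        cluster_names = [c for c, k in zip(cluster_names, keep) if k]

    observed = _log2_fd(counts_a, counts_b)

    # permutation null: shuffle the condition labels at fixed group sizes.
    # The permuted group is always the lexicographically second level, so the
    # null draws do not depend on which level the caller named A or B and
    # swapping the two leaves every p-value unchanged.
    rng = substream(seed, "proportion_perm")
    n = len(clusters)
    n_second = int((conditions == levels[1]).sum())
    null_abs = np.empty((n_perm, len(cluster_names)))
    base = np.zeros(n, dtype=bool)
    base[:n_second] = True
    total_counts = counts_a + counts_b
    for i in range(n_perm):
        perm = rng.permutation(base)
        c2 = C[perm].sum(axis=0)
        c1 = total_counts - c2
        null_abs[i] = np.abs(_log2_fd(c1, c2))

    tol = 1e-12
    pvals = (1.0 + (null_abs >= np.abs(observed)[None, :] - tol).sum(axis=0)) / (
        n_perm + 1.0
    )

    # percentile bootstrap within each condition (resampling cells with
    # replacement is a multinomial draw over clusters)
    brng = substream(seed, "proportion_boot")
    pa_hat = counts_a / counts_a.sum()
    pb_hat = counts_b / counts_b.sum()
    boot_a = brng.multinomial(int(counts_a.sum()), pa_hat, size=n_boot)
    boot_b = brng.multinomial(int(counts_b.sum()), pb_hat, size=n_boot)
    boot_stats = np.array(
        [_log2_fd(a, b) for a, b in zip(boot_a, boot_b)]
    )
    ci_lo = np.percentile(boot_stats, 2.5, axis=0)
    ci_hi = np.percentile(boot_stats, 97.5, axis=0)

    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "cluster": cluster_names,
            "n_a": counts_a.astype(int),
            "n_b": counts_b.astype(int),
            "log2_fold_difference": observed,
            "pvalue": pvals,
            "ci_lower": ci_lo,
            "ci_upper": ci_hi,
            "fdr": fdr,
        }
    )


def abundance_timecourse(
    metadata: pd.DataFrame,
    cluster_col: str = "cluster",
    timepoint_col: str = "timepoint",
    timepoint_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format per-timepoint cluster fractions (each timepoint sums to 1)."""
    if timepoint_order is None:
        timepoint_order = list(pd.unique(metadata[timepoint_col]))
    rows = []
    for tp in timepoint_order:
        sub = metadata[metadata[timepoint_col] == tp]
        if len(sub) == 0:
            warnings.warn(f"timepoint {tp} has no cells; omitted")
            continue
        fracs = sub[cluster_col].value_counts(normalize=True)
        for cl, f in fracs.items():
            rows.append(
                {
                    "timepoint": tp,
                    "cluster": cl,
                    "fraction": f,
                    "n_cells": int((sub[cluster_col] == cl).sum()),
                }
            )
    return pd.DataFrame(rows)
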