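"""Gene-module scoring with expression-binned control genes, and pseudobulk trends.

The module score of a cell is the mean normalized expression of the gene set
minus the mean expression of control genes sampled from the same
average-expression bins — the standard binned-control scheme.  Subtracting
bin-matched controls cancels both per-cell shifts and the set's average
expression level, so the score reflects set-specific activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr

from ._rng import substream


@dataclass
class ModuleScoreParams:
    n_bins: int = 24
    n_ctrl_per_gene: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.n_ctrl_per_gene < 1:
            raise ValueError("n_bins and n_ctrl_per_gene must be >= 1")


def _dense_norm(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def module_score(
    adata: ad.AnnData,
    gene_set: Sequence[str],
    params: ModuleScoreParams | None = None,
) -> pd.Series:
    """Per-cell module score for ``gene_set`` on normalized expression.

    Genes are split into ``n_bins`` equal-frequency bins of average
    expression; each set gene draws ``n_ctrl_per_gene`` control genes from
    its bin (seeded, without replacement when the bin allows).  Controls
    exclude the set genes themselves whenever the bin contains any
    alternative.  Raises ``ValueError`` on an empty set or when every set
    gene is missing from the matrix.
    """
    params = params or ModuleScoreParams()
    if len(gene_set) == 0:
        raise ValueError("gene_set is empty")
    present = [g for g in gene_set if g in adata.var_names]
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValueError(f"no gene of the set is present in the matrix: {missing}")
    if missing:
        warnings.warn(f"module genes missing from matrix, skipped: {missing}")

    X = _dense_norm(adata)
    genes = adata.var_names.to_numpy()
    avg = X.mean(axis=0)

    n_bins = min(params.n_bins, len(genes))
    # equal-frequency bins on the rank of average expression
    ranks = pd.Series(avg, index=genes).rank(method="first")
    bins = pd.qcut(ranks, q=n_bins, labels=False)

    rng = substream(params.seed, "module_score")
    set_idx = np.array([np.where(genes == g)[0][0] for g in present])
    in_set = np.zeros(len(genes), dtype=bool)
    in_set[set_idx] = True

    ctrl: set[int] = set()
    for gi in set_idx:
        bin_members = np.where(bins.to_numpy() == bins.iloc[gi])[0]
        candidates = bin_members[~in_set[bin_members]]
        if len(candidates) == 0:
            candidates = bin_members  # degenerate: the set fills the bin
        k = min(params.n_ctrl_per_gene, len(candidates))
        ctrl.update(rng.choice(candidates, size=k, replace=False).tolist())
    ctrl_idx = np.array(sorted(ctrl))

    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name="module_score")


def pseudobulk_trend(
    adata: ad.AnnData,
    metadata: pd.DataFrame,
    genes: Sequence[str],
    timepoint_col: str = "timepoint",
    timepoint_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean normalized expression per gene per timepoint, with trend report.

    Returns a long table (gene, timepoint, mean expression) and a per-gene
    Spearman correlation of the pseudobulk mean against timepoint rank
    (NA with a single timepoint).  Unknown genes are listed in a warning and
    skipped.
    """
    known = [g for g in genes if g in adata.var_names]
    unknown = [g for g in genes if g not in adata.var_names]
    if unknown:
        warnings.warn(f"genes not in matrix, skipped: {unknown}")
    if not known:
        raise ValueError("no requested gene present in the matrix")

    tps = metadata.loc[adata.obs_names, timepoint_col]
    if timepoint_order is None:
        timepoint_order = list(pd.unique(tps))
    X = _dense_norm(adata[:, known])

    rows = []
    for tp in timepoint_order:
        mask = (tps == tp).to_numpy()
        if not mask.any():
            warnings.warn(f"timepoint {tp} has no cells; omitted")
            continue
        means = X[mask].mean(axis=0)
        for g, m in zip(known, means):
            rows.append({"gene": g, "timepoint": tp, "mean_expression": m})
    table = pd.DataFrame(rows)

    trend_rows = []
    for g, grp in table.groupby("gene", sort=False):
        ordered = grp.set_index("timepoint").reindex(
            [tp for tp in timepoint_order if tp in grp["timepoint"].values]
        )
        y = ordered["mean_expression"].to_numpy()
        if len(y) < 2 or np.allclose(y, y[0]):
            rho = 0.0 if (len(y) >= 2) else np.nan
        else:
            rho = spearmanr(np.arange(len(y)), y).statistic
        trend_rows.append({"gene": g, "spearman_trend": rho})
    return table, pd.DataFrame(trend_rows)
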