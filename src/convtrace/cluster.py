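"""Graph clustering, marker-based annotation and differential expression.

Cells are embedded by PCA on scaled highly-variable genes, connected in a
k-nearest-neighbour graph and partitioned by Louvain community detection at a
configurable resolution (default 0.3 on 25 components, mirroring the
conventional single-cell workflow).  Cluster labels are renumbered by
descending size so that label 0 is always the largest community.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import anndata as ad
import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from ._rng import derive_seed
from .scoring import ModuleScoreParams, module_score


@dataclass
class ClusterResult:
    labels: pd.Series  # per-cell cluster label (int, ordered by size)
    markers: pd.DataFrame | None = None
    annotation: Dict[int, str] = field(default_factory=dict)


def _scaled_pcs(
    adata: ad.AnnData, hvg: Sequence[str], n_pcs: int, seed: int, clip: float = 10.0
) -> np.ndarray:
    X = adata[:, list(hvg)].X
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -clip, clip)
    n_pcs = min(n_pcs, Z.shape[0] - 1, Z.shape[1])
    return PCA(n_components=n_pcs, random_state=seed).fit_transform(Z)


def cluster_cells(
    adata: ad.AnnData,
    hvg: Sequence[str],
    n_pcs: int = 25,
    resolution: float = 0.3,
    k_neighbors: int = 20,
    seed: int = 0,
) -> ClusterResult:
    """Louvain clustering on the kNN graph of the PCA embedding.

    Deterministic for a fixed seed.  Raises ``ValueError`` when there are
    fewer cells than ``k_neighbors``.
    """
    if adata.n_obs <= k_neighbors:
        raise ValueError(
            f"{adata.n_obs} cells but k_neighbors={k_neighbors}; reduce k"
        )
    pcs = _scaled_pcs(adata, hvg, n_pcs, seed)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {
        (min(i, j), max(i, j))
        for i, row in enumerate(idx)
        for j in row[1:]  # drop self
    }
    graph = igraph.Graph(n=adata.n_obs, edges=sorted(edges))

    random.seed(derive_seed(seed, "louvain"))  # igraph draws from python's RNG
    membership = graph.community_multilevel(resolution=resolution).membership
    labels = pd.Series(membership, index=adata.obs_names, name="cluster")

    # renumber by descending cluster size (ties by old label) for stable names
    sizes = labels.value_counts()
    remap = {
        old: new
        for new, old in enumerate(
            sorted(sizes.index, key=lambda c: (-sizes[c], c))
        )
    }
    labels = labels.map(remap)
    return ClusterResult(labels=labels)


def annotate_clusters(
    adata: ad.AnnData,
    labels: pd.Series,
    marker_spec: Dict[str, Sequence[str]],
    score_params: ModuleScoreParams | None = None,
) -> Dict[int, str]:
    """Label each cluster by its best-scoring reference marker set.

    Every reference set is scored per cell with the binned-control module
    score; each cluster takes the name of the set with the highest mean
    score, ties broken by the order the sets are listed (and logged).
    Raises ``ValueError`` if a reference set has no gene in the matrix.
    """
    if not marker_spec:
        raise ValueError("marker_spec is empty")
    missing = {
        name: [g for g in genes if g not in adata.var_names]
        for name, genes in marker_spec.items()
    }
    fully_missing = {n: m for n, m in missing.items() if len(m) == len(marker_spec[n])}
    if fully_missing:
        raise ValueError(f"marker genes absent from matrix: {fully_missing}")

    scores = pd.DataFrame(
        {
            name: module_score(adata, list(genes), score_params)
            for name, genes in marker_spec.items()
        }
    )
    names = list(marker_spec)
    annotation: Dict[int, str] = {}
    for cl in sorted(labels.unique()):
        means = scores.loc[labels[labels == cl].index].mean(axis=0)
        best = means.max()
        winners = [n for n in names if np.isclose(means[n], best)]
        if len(winners) > 1:
            warnings.warn(f"cluster {cl}: tie between {winners}; using {winners[0]}")
        annotation[int(cl)] = winners[0]
    return annotation


def de_wilcoxon(
    adata: ad.AnnData,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum differential expression, BH-corrected.

    Per gene: rank-sum p of group A vs group B on normalized expression,
    log2 fold-change of group means, Benjamini-Hochberg adjustment across all
    tested genes, significance flag at adjusted p < ``alpha``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    A = adata[list(group_a)].X
    B = adata[list(group_b)].X
    A = A.toarray() if sp.issparse(A) else np.asarray(A, float)
    B = B.toarray() if sp.issparse(B) else np.asarray(B, float)

    res = mannwhitneyu(A, B, axis=0, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)

    eps = 1e-9
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    lfc = np.log2((mean_a + eps) / (mean_b + eps))

    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "gene": adata.var_names,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": lfc,
            "pvalue": pvals,
            "padj": padj,
        }
    )
    out["significant"] = out["padj"] < alpha
    return out.sort_values(["pvalue", "gene"]).reset_index(drop=True)


def cluster_markers(
    adata: ad.AnnData, labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One-vs-rest marker table for every cluster (rank-sum + BH per cluster)."""
    tables = []
    for cl in sorted(labels.unique()):
        in_cl = labels.index[labels == cl]
        rest = labels.index[labels != cl]
        if len(in_cl) < 2 or len(rest) < 2:
            warnings.warn(f"cluster {cl} too small for DE; skipped")
            continue
        tab = de_wilcoxon(adata, in_cl, rest, alpha=alpha)
        tab.insert(0, "cluster", cl)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)
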