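"""Quality filtering, normalization and highly-variable-gene selection.

QC keeps cells with an inclusive detected-gene window (default 1,000-12,000
genes) and excludes cells with strictly more than the allowed mitochondrial
fraction (default 1%).  Normalization scales each cell to a common total and
applies log1p; transgene features are excluded from the per-cell total so
that viral load does not distort endogenous expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as ctio


@dataclass
class QCThresholds:
    min_genes: int = 1000
    max_genes: int = 12000
    max_mito_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.min_genes <= self.max_genes:
            raise ValueError("require 0 < min_genes <= max_genes")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in [0,1]")


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    return sp.csr_matrix(adata.layers.get("counts", adata.X))


def _endogenous_mask(adata: ad.AnnData) -> np.ndarray:
    classes = adata.var.get(
        "feature_class", pd.Series(ctio.GENE_CLASS, index=adata.var_names)
    )
    return (classes != ctio.TRANSGENE_CLASS).to_numpy()


def qc_filter(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> Tuple[ad.AnnData, dict]:
    """Filter cells on detected genes and mitochondrial fraction.

    A cell is retained when ``min_genes <= detected genes <= max_genes``
    (bounds inclusive) and its mitochondrial read fraction does not exceed
    ``max_mito_fraction`` (strictly-above is excluded).  Transgene features
    count toward neither rule.  Returns the filtered matrix and a report with
    per-rule removal counts and survivor medians.
    """
    thresholds = thresholds or QCThresholds()
    X = _counts(adata)
    endo = _endogenous_mask(adata)
    Xe = X[:, endo]

    detected = np.asarray((Xe > 0).sum(axis=1)).ravel()
    total = np.asarray(Xe.sum(axis=1)).ravel()

    classes = adata.var.get(
        "feature_class", pd.Series(ctio.GENE_CLASS, index=adata.var_names)
    )
    mito_mask = (classes == ctio.MITO_CLASS).to_numpy()
    if not mito_mask.any():
        # fall back to the conventional name prefix
        mito_mask = np.asarray(adata.var_names.str.upper().str.startswith("MT-"))
    if mito_mask.any():
        mito_total = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
        pass_mito = mito_frac <= thresholds.max_mito_fraction
        mito_skipped = False
    else:
        warnings.warn("no mitochondrial features found; mito rule skipped")
        mito_frac = np.zeros(adata.n_obs)
        pass_mito = np.ones(adata.n_obs, dtype=bool)
        mito_skipped = True

    pass_low = detected >= thresholds.min_genes
    pass_high = detected <= thresholds.max_genes
    keep = pass_low & pass_high & pass_mito

    report = {
        "n_input": int(adata.n_obs),
        "n_retained": int(keep.sum()),
        "removed_low_genes": int((~pass_low).sum()),
        "removed_high_genes": int((~pass_high).sum()),
        "removed_mito": int((~pass_mito).sum()),
        "mito_rule_skipped": mito_skipped,
        "median_umi": float(np.median(total[keep])) if keep.any() else 0.0,
        "median_genes": float(np.median(detected[keep])) if keep.any() else 0.0,
        "doublet_rule": "not applied",  # doublet detection out of scope
    }
    out = adata[keep].copy()
    out.obs["n_genes_detected"] = detected[keep]
    out.obs["total_umi"] = total[keep]
    out.obs["mito_fraction"] = mito_frac[keep]
    return out, report


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Library-size normalize to ``target_sum`` per cell, then log1p.

    The per-cell total excludes transgene features, so cells with heavy viral
    load are not artificially shrunk; transgene values themselves are scaled
    with the same cell factor.  Cells with a zero endogenous total are
    removed with a warning.
    """
    X = _counts(adata).astype(np.float64)
    endo = _endogenous_mask(adata)
    totals = np.asarray(X[:, endo].sum(axis=1)).ravel()
    nonzero = totals > 0
    if not nonzero.all():
        warnings.warn(f"removing {int((~nonzero).sum())} cells with zero total")
    adata = adata[nonzero].copy()
    X = X[nonzero]
    totals = totals[nonzero]

    scale = sp.diags(target_sum / totals)
    norm = scale @ X
    norm.data = np.log1p(norm.data)
    out = adata
    out.layers["counts"] = _counts(adata)
    out.X = sp.csr_matrix(norm)
    out.uns["normalization"] = {"target_sum": target_sum, "log1p": True}
    return out


def select_hvg(adata: ad.AnnData, n_hvg: int = 4000) -> list[str]:
    """Rank genes by variance-stabilized dispersion and return the top n_hvg.

    Follows the vst scheme: fit a mean-variance trend on raw counts (in log10
    space), standardize each gene by its fitted standard deviation, clip at
    sqrt(n_cells), and rank genes by the variance of the clipped values.
    Ties break by gene identifier, so the selection is fully deterministic.
    Transgene features are never selected.
    """
    X = _counts(adata).astype(np.float64)
    endo = _endogenous_mask(adata)
    genes = adata.var_names[endo]
    X = sp.csc_matrix(X[:, endo])
    n = X.shape[0]

    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)

    usable = (mean > 0) & (var > 0)
    if usable.sum() < 3:
        order = np.argsort(-var, kind="stable")
        ranked = [genes[i] for i in order if var[i] > 0]
        return ranked[:n_hvg]

    logm, logv = np.log10(mean[usable]), np.log10(var[usable])
    coef = np.polyfit(logm, logv, deg=2)
    fitted_sd = np.sqrt(10 ** np.polyval(coef, np.log10(np.where(mean > 0, mean, 1.0))))
    fitted_sd[~usable] = np.inf  # constant genes get zero standardized variance

    clip = np.sqrt(n)
    # variance of clipped standardized counts, computed column-wise
    Xd = X.toarray()
    z = (Xd - mean) / fitted_sd
    np.clip(z, -clip, clip, out=z)
    std_var = z.var(axis=0, ddof=1)
    std_var[~usable] = 0.0

    order = pd.DataFrame({"v": std_var, "g": genes}).sort_values(
        ["v", "g"], ascending=[False, True]
    )
    order = order[order["v"] > 0]
    if n_hvg > len(order):
        warnings.warn(
            f"requested {n_hvg} HVGs but only {len(order)} variable genes present"
        )
    return order["g"].head(n_hvg).tolist()
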