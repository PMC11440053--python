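"""Readers and writers for the 10x-style formats used throughout the pipeline.

The on-disk count format is the MTX triplet (``matrix.mtx[.gz]``,
``barcodes.tsv[.gz]``, ``features.tsv[.gz]``).  ``features.tsv`` carries a
third column with the feature class — ``Gene Expression``, ``Transgene`` or
``Mito`` — a conservative extension of the 10x dialect that lets downstream
stages treat transgenes and mitochondrial features specially without name
heuristics.
"""

from __future__ import annotations

import gzip
import os
from typing import IO, Iterator, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

GENE_CLASS = "Gene Expression"
TRANSGENE_CLASS = "Transgene"
MITO_CLASS = "Mito"


def _open_text(path: str, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(path_dir: str, stem: str) -> str:
    for suffix in ("", ".gz"):
        candidate = os.path.join(path_dir, stem + suffix)
        if os.path.exists(candidate):
            return candidate
    raise FileNotFoundError(f"{stem}[.gz] not found in {path_dir}")


def read_mtx_dir(path: str) -> ad.AnnData:
    """Read an MTX triplet directory into an AnnData (cells x features).

    Raises ``ValueError`` when the matrix dimensions disagree with the
    barcode or feature file.
    """
    mtx_path = _find(path, "matrix.mtx")
    try:
        with _open_text(mtx_path, "rb" if mtx_path.endswith(".gz") else "r") as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise ValueError(f"malformed MTX file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat).T.tocsr()  # stored features x cells, as 10x does

    barcodes = pd.read_csv(_find(path, "barcodes.tsv"), sep="\t", header=None)
    features = pd.read_csv(_find(path, "features.tsv"), sep="\t", header=None)
    if mat.shape[0] != len(barcodes):
        raise ValueError(
            f"matrix has {mat.shape[0]} cells but barcodes.tsv has {len(barcodes)}"
        )
    if mat.shape[1] != len(features):
        raise ValueError(
            f"matrix has {mat.shape[1]} features but features.tsv has {len(features)}"
        )

    var = pd.DataFrame(index=pd.Index(features[0].astype(str).to_numpy()))
    var["gene_symbol"] = (
        features[1].astype(str).values if features.shape[1] > 1 else var.index
    )
    var["feature_class"] = (
        features[2].astype(str).values if features.shape[1] > 2 else GENE_CLASS
    )
    obs = pd.DataFrame(index=pd.Index(barcodes[0].astype(str).to_numpy()))
    adata = ad.AnnData(X=mat, obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    return adata


def write_mtx_dir(adata: ad.AnnData, path: str, compress: bool = False) -> None:
    """Write an AnnData as an MTX triplet (counts layer if present, else X)."""
    os.makedirs(path, exist_ok=True)
    mat = adata.layers.get("counts", adata.X)
    mat = sp.csc_matrix(mat).T  # features x cells on disk
    suffix = ".gz" if compress else ""

    mtx_path = os.path.join(path, "matrix.mtx" + suffix)
    if compress:
        with gzip.open(mtx_path, "wb") as fh:
            scipy.io.mmwrite(fh, mat)
    else:
        scipy.io.mmwrite(mtx_path, mat)

    with _open_text(os.path.join(path, "barcodes.tsv" + suffix), "wt") as fh:
        for bc in adata.obs_names:
            fh.write(f"{bc}\n")
    with _open_text(os.path.join(path, "features.tsv" + suffix), "wt") as fh:
        symbols = adata.var.get("gene_symbol", pd.Series(adata.var_names, index=adata.var_names))
        classes = adata.var.get(
            "feature_class", pd.Series(GENE_CLASS, index=adata.var_names)
        )
        for name in adata.var_names:
            fh.write(f"{name}\t{symbols[name]}\t{classes[name]}\n")


def read_fastq_pair(r1_path: str, r2_path: str) -> Iterator[Tuple[str, str, str]]:
    """Iterate paired reads in lock-step as (read_id, seq1, seq2).

    Raises ``ValueError`` (with the read index) if the files are unpaired or
    truncated relative to each other, or if read names disagree.
    """
    import pysam

    with pysam.FastxFile(r1_path) as f1, pysam.FastxFile(r2_path) as f2:
        i = 0
        it1, it2 = iter(f1), iter(f2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise ValueError(f"FASTQ pair truncated at read index {i}")
            if rec1.name != rec2.name:
                raise ValueError(
                    f"FASTQ pair mismatch at read index {i}: "
                    f"{rec1.name!r} vs {rec2.name!r}"
                )
            yield rec1.name, rec1.sequence, rec2.sequence
            i += 1


def write_table(df: pd.DataFrame, path: str, stage: str, params: dict | None = None) -> None:
    """Write a TSV with a one-line header comment declaring stage + parameters."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    param_str = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    with open(path, "w") as fh:
        fh.write(f"# convtrace stage={stage} {param_str}".rstrip() + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_metadata(path: str) -> pd.DataFrame:
    """Per-cell metadata TSV: first column is the cell barcode (index)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index(df.columns[0])
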