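#!/usr/bin/env python
"""QC, normalization, clustering and annotation of the synthetic experiment.

Filters nuclei on detected genes and mitochondrial fraction, normalizes,
selects highly variable genes, clusters the kNN graph with Louvain and
annotates clusters by marker-set module scores. Writes per-cell labels and
per-cluster marker tables under results/.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from convtrace import (
    QCThresholds,
    annotate_clusters,
    cluster_cells,
    cluster_markers,
    normalize_log,
    qc_filter,
    select_hvg,
)
from convtrace.io import read_metadata, read_mtx_dir, write_table
from convtrace.simulate import DEFAULT_MARKERS

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
DATA = os.path.join(os.path.dirname(__file__), "..", "scratch", "data")


def main() -> None:
    os.makedirs(BASE, exist_ok=True)
    adata = read_mtx_dir(os.path.join(DATA, "counts"))
    adata.obs = adata.obs.join(read_metadata(os.path.join(DATA, "metadata.tsv")))

    adata, report = qc_filter(adata, QCThresholds())
    print(f"QC: kept {report['n_retained']}/{report['n_input']} nuclei "
          f"(median {report['median_genes']:.0f} genes, "
          f"{report['median_umi']:.0f} UMIs)")
    with open(os.path.join(BASE, "qc_report.json"), "w") as fh:
        json.dump(report, fh, indent=2)

    adata = normalize_log(adata)
    hvg = select_hvg(adata, n_hvg=2000)
    result = cluster_cells(adata, hvg, n_pcs=25, resolution=0.3,
                           k_neighbors=20, seed=0)
    spec = {k: [g for g in v if g in adata.var_names]
            for k, v in DEFAULT_MARKERS.items()}
    annotation = annotate_clusters(adata, result.labels, spec)
    print(f"clustering: {result.labels.nunique()} clusters -> {annotation}")

    labels = pd.DataFrame(
        {
            "cell": result.labels.index,
            "cluster": result.labels.to_numpy(),
            "annotation": result.labels.map(annotation).to_numpy(),
            "timepoint": adata.obs["timepoint"].to_numpy(),
            "condition": adata.obs["condition"].to_numpy(),
        }
    )
    write_table(labels, os.path.join(BASE, "cluster_labels.tsv"), "cluster",
                {"resolution": 0.3, "n_pcs": 25})

    markers = cluster_markers(adata, result.labels)
    top = markers[markers["significant"]].groupby("cluster").head(20)
    write_table(top, os.path.join(BASE, "cluster_markers.tsv"), "markers")
    print(f"marker table: {int(markers['significant'].sum())} significant "
          f"cluster/gene pairs; top 20 per cluster written")


if __name__ == "__main__":
    main()
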