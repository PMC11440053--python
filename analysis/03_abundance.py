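#!/usr/bin/env python
"""Differential cluster abundance and the neuronal time course.

Two permutation tests: (a) two halves of the starting population, a
technical-replicate style null where no cluster should shift; (b) D0
against the pooled early conversion window (D2-D7), where the neuronal
cluster should dominate. Also writes per-timepoint cluster fractions.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import numpy as np

from convtrace import abundance_timecourse, permutation_proportion_test
from convtrace.io import read_table, write_table

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
POST = ("D2", "D3", "D5", "D7")


def main() -> None:
    os.makedirs(BASE, exist_ok=True)
    labels = read_table(os.path.join(BASE, "cluster_labels.tsv"))

    # (a) split D0 into two pseudo-replicates
    d0 = labels[labels["timepoint"] == "D0"].reset_index(drop=True)
    half = np.arange(len(d0)) % 2 == 0
    rep = permutation_proportion_test(
        d0["annotation"], np.where(half, "rep1", "rep2"),
        n_perm=1000, n_boot=1000, seed=1,
    )
    write_table(rep, os.path.join(BASE, "proportions_d0_replicates.tsv"),
                "proportions", {"comparison": "D0 split halves"})
    print("replicate null: min FDR =", round(rep["fdr"].min(), 3),
          "(no cluster should be significant)")

    # (b) D0 vs pooled D2-D7
    sub = labels[labels["timepoint"].isin(("D0",) + POST)]
    cond = np.where(sub["timepoint"] == "D0", "A_D0", "B_D2toD7")
    res = permutation_proportion_test(
        sub["annotation"], cond, n_perm=1000, n_boot=1000, seed=2,
    )
    write_table(res, os.path.join(BASE, "proportions_d0_vs_post.tsv"),
                "proportions", {"comparison": "D0 vs pooled D2-D7"})
    hits = res[res["fdr"] < 0.05]
    print("D0 vs D2-D7: significant clusters at FDR<0.05:")
    print(hits[["cluster", "log2_fold_difference", "fdr"]].to_string(index=False))

    tc = abundance_timecourse(
        labels.set_index("cell"), cluster_col="annotation",
        timepoint_order=["D0", "D2", "D3", "D5", "D7", "D14", "D21"],
    )
    write_table(tc, os.path.join(BASE, "abundance_timecourse.tsv"), "proportions")
    neurons = tc[tc["cluster"] == "neuron"].set_index("timepoint")["fraction"]
    print("\nneuronal fraction by timepoint:")
    print((neurons * 100).round(1).to_string())


if __name__ == "__main__":
    main()
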