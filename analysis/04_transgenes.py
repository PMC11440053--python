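#!/usr/bin/env python
"""Transgene co-expression and its relationship to conversion outcome.

Calls TF-positive cells (>=1 UMI per factor), compares the neuron fraction
of cells co-expressing all three factors against partially transduced cells
(Fisher's exact test), compares transgene levels within the neuronal
cluster, and scores a neuronal-maturation gene module across TF groups.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from convtrace import (
    ModuleScoreParams,
    call_tf_positive,
    maturation_by_group,
    module_score,
    neuron_fraction_by_group,
    normalize_log,
    qc_filter,
    transgene_level_by_group,
)
from convtrace.io import read_metadata, read_mtx_dir, read_table, write_table
from convtrace.simulate import DEFAULT_MARKERS

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
DATA = os.path.join(os.path.dirname(__file__), "..", "scratch", "data")


def main() -> None:
    os.makedirs(BASE, exist_ok=True)
    adata = read_mtx_dir(os.path.join(DATA, "counts"))
    adata.obs = adata.obs.join(read_metadata(os.path.join(DATA, "metadata.tsv")))
    labels = read_table(os.path.join(BASE, "cluster_labels.tsv")).set_index("cell")

    adata, _ = qc_filter(adata)
    adata = adata[adata.obs_names.isin(labels.index)].copy()
    adata.obs["annotation"] = labels.loc[adata.obs_names, "annotation"]
    adata = normalize_log(adata)

    # restrict the outcome analysis to the conversion window
    post = adata[adata.obs["timepoint"] != "D0"]
    calls = call_tf_positive(post)
    is_neuron = post.obs["annotation"] == "neuron"
    fisher = neuron_fraction_by_group(calls, is_neuron)
    print(
        f"neuron fraction: all three TF {fisher['fraction_all_three']:.0%} vs "
        f"partial {fisher['fraction_partial']:.0%} "
        f"(Fisher p = {fisher['fisher_p']:.2e})"
    )
    with open(os.path.join(BASE, "tf_contingency.json"), "w") as fh:
        json.dump(
            {
                "table": fisher["table"].tolist(),
                "fraction_all_three": fisher["fraction_all_three"],
                "fraction_partial": fisher["fraction_partial"],
                "fisher_p": fisher["fisher_p"],
            },
            fh, indent=2,
        )

    neuron_cells = post.obs_names[is_neuron.to_numpy()]
    levels = transgene_level_by_group(post, calls, neuron_cells)
    write_table(levels, os.path.join(BASE, "transgene_levels.tsv"), "transgenes")
    print("\ntransgene expression in the neuronal cluster (all three vs partial):")
    print(levels.to_string(index=False))

    scores = module_score(post, list(DEFAULT_MARKERS["neuron"]),
                          ModuleScoreParams(seed=0))
    mat = maturation_by_group(scores, calls)
    print("\nmaturation module score by TF group:")
    for grp, stats in mat["groups"].items():
        print(f"  {grp:10s} n={stats['n']:5d} median={stats['median']:.3f}")
    print(f"  none vs any: p = {mat['none_vs_any']['pvalue']:.2e}; "
          f"any vs all three: p = {mat['any_vs_all_three']['pvalue']:.2e}")
    calls_out = calls.copy()
    calls_out.insert(0, "cell", calls_out.index)
    write_table(calls_out, os.path.join(BASE, "tf_calls.tsv"), "transgenes")

    # The default dataset draws conversion independently of transgene load,
    # so the Fisher test above is a null check.  Re-simulate with conversion
    # probability tied to the TF group to show the analysis recovers a
    # planted dependence (86% vs 69% neuron fractions).
    from convtrace import SimConfig, simulate_counts, simulate_transgenes

    cfg = SimConfig(
        n_cells_per_timepoint=2000, timepoints=("D0", "D7"),
        conversion_by_tf_group={"none": 0.2, "partial": 0.69, "all_three": 0.86},
        seed=20240905,
    )
    sim, truth = simulate_counts(cfg)
    sim = simulate_transgenes(cfg, sim, truth)
    post_mask = (truth["timepoint"] == "D7").to_numpy()
    calls2 = call_tf_positive(sim[post_mask])
    fisher2 = neuron_fraction_by_group(calls2, truth.loc[post_mask, "is_neuron"])
    print(
        f"\nTF-dependent scenario (planted 86% vs 69%): recovered "
        f"{fisher2['fraction_all_three']:.0%} vs {fisher2['fraction_partial']:.0%} "
        f"(Fisher p = {fisher2['fisher_p']:.2e})"
    )


if __name__ == "__main__":
    main()
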