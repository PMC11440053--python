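#!/usr/bin/env python
"""Generate the synthetic conversion experiment used by the analysis scripts.

Seven timepoints (D0 through D21), 1,000 cells each, five glial
subpopulations at D0 and a neuronal fraction growing to 76% by D21; three
conversion-factor transgenes at MOI 1.5; 66 lineage clones captured in
barcode reads for ~60% of cells. Writes the count matrix, metadata,
whitelist, FASTQ pair and the ground-truth table under results/data/.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from convtrace import SimConfig, simulate_dataset

# raw matrices and FASTQs are large; they live under scratch/, while
# the downstream scripts write their summary tables under results/
OUT = os.path.join(os.path.dirname(__file__), "..", "scratch", "data")


def main() -> None:
    config = SimConfig(n_cells_per_timepoint=1000, seed=20240904)
    paths = simulate_dataset(config, OUT)
    print("wrote synthetic dataset:")
    print(json.dumps(paths, indent=2))
    print(
        f"\n{config.n_cells_per_timepoint} cells x {len(config.timepoints)} "
        f"timepoints; {config.n_clones} clones; MOI {config.moi} per factor"
    )


if __name__ == "__main__":
    main()
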