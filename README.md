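# convtrace

Analysis pipeline for single-nucleus RNA-seq studies of **direct
glia-to-neuron conversion**, with a ground-truthed synthetic-data generator.
It targets experiments in which human glial progenitor cells (hGPCs/OPCs)
are reprogrammed into induced dopamine neurons by forced expression of three
transcription factors (Ascl1, Lmx1a, Nurr1) delivered on separate lentiviral
vectors, while a pooled lentiviral barcode library tags clonal lineages.

The package answers the questions such a study asks of its data:

1. **Composition** — which glial subpopulations are present at the start,
   and does their abundance shift between conditions?  Clusters come from
   Louvain community detection on a kNN graph of PCA-embedded cells;
   differential abundance uses a permutation test of per-cluster proportions
   with the statistic `log2(p̂_B,c / p̂_A,c)` (0.5 pseudo-cells per
   cluster×condition count), permutation p-values
   `(1 + #{|t*| ≥ |t|}) / (n_perm + 1)`, percentile-bootstrap CIs, and
   Benjamini–Hochberg adjustment across clusters.
2. **Transgene dose and outcome** — cells are TF-positive at ≥1 UMI per
   transgene; the neuron fraction of cells co-expressing all three factors
   is compared with partially transduced cells by Fisher's exact test, and
   neuronal maturation is scored with a binned-control gene-module score
   (mean expression of the set minus bin-matched random controls).
3. **Lineage** — 20-nt viral barcodes are pulled from read pairs matching
   the cassette motif `GTCGTGA[ACGT]{20}CTCGAC` (plus a 12-nt library ID),
   error-corrected within each cell by directional edit-distance-1 collapse,
   whitelist-filtered, and grouped into clones.  Per-clone conversion is
   modeled by no-intercept weighted least squares of the clone's post-
   induction neuron fraction on its D0 cluster composition
   (`y_j = Σ_c x_jc β_c + ε_j`, compositions on the simplex), so each
   coefficient β_c is the conversion rate of starting cluster *c*; an F
   contrast tests whether all rates are equal.

The synthetic generator plants all of this structure — five OPC
subpopulations with marker genes, a neuronal population growing over the
time course, Poisson(MOI) transgene copies, clone-structured barcode reads
with sequencing errors and decoy reads — and emits the ground truth to a
separate file that no analysis stage reads.

## Worked example

Run the numbered analysis scripts in order (they share
`scratch/data/` for the raw simulated dataset and write tables under
`results/`):

```bash
python analysis/01_simulate.py      # 7 timepoints x 1,000 cells, 66 clones
python analysis/02_qc_cluster.py    # QC, Louvain clustering, annotation
python analysis/03_abundance.py     # permutation proportion tests, timecourse
python analysis/04_transgenes.py    # TF calls, Fisher test, module scores
python analysis/05_lineage.py       # barcode pipeline + conversion model
```

Output actually printed by these scripts on the default seed:

```
QC: kept 6964/7000 nuclei (median 1371 genes, 4986 UMIs)
clustering: 6 clusters -> {0: 'neuron', 1: 'OPC1', 2: 'OPC3', 3: 'OPC2', 4: 'OPC5', 5: 'OPC4'}

neuronal fraction by timepoint:
D2 20.3  D3 30.0  D5 38.3  D7 48.3  D14 66.0  D21 76.9

TF-dependent scenario (planted 86% vs 69%): recovered 85% vs 69% (Fisher p = 7.05e-19)

detection: barcode assigned in 58% of cells [0.573, 0.596]
clones: 75 detected, 51 present both before and after conversion
equality of rates: F = 1.22, p = 0.315 (no evidence that any glial
subpopulation converts preferentially)
```

Reading: the five planted glial subpopulations and the growing neuronal
cluster are recovered; the replicate-split permutation test finds no
differential abundance (all FDR > 0.05) while D0 vs D2–D7 flags the neuronal
cluster; the lineage model, fitted on clones spanning both sides of
induction, finds per-cluster conversion rates statistically
indistinguishable — the planted null, since the generator converts all
clusters at the same rate.

The same stages are available as a CLI (`convtrace simulate|qc|cluster|
score|proportions|transgenes|barcodes|clonal|run-all`) and as library
functions (`convtrace.simulate`, `convtrace.preprocess`,
`convtrace.cluster`, `convtrace.proportions`, `convtrace.transgenes`,
`convtrace.barcodes`, `convtrace.clonal`, `convtrace.pipeline`).

## Layout

```
src/convtrace/      library: generator, QC/clustering, proportion test,
                    transgene analysis, barcode pipeline, clonal model, CLI
analysis/           numbered narrative drivers (simulate -> ... -> lineage)
tests/              unit, property and acceptance tests (pytest)
scripts/acceptance.py
docs/methods.md     model and design notes
```
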