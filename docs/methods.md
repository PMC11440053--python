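# Methods

## Scope and model of the experiment

`convtrace` models a 3D glia-to-neuron conversion experiment profiled by
single-nucleus RNA-seq: a starting population of human glial progenitor
cells (five OPC subpopulations), transduction with three doxycycline-
inducible conversion-factor vectors (Ascl1, Lmx1a, Nurr1), a neuronal
population that appears within days and grows over a D0→D21 time course,
and a pooled lentiviral barcode library that tags clonal lineages so that
per-clone conversion can be measured.

## Synthetic data generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the tests.

**Counts.** UMI counts are negative binomial per gene
(`NB(mean = μ_gc · s_i, size = dispersion)`), with per-gene baseline means
drawn log-normally, a log-normal per-cell size factor
(σ = 0.25), and population-specific profiles: each population's marker
genes are elevated `marker_fold`-fold (default 8); neurons down-weight all
glial markers (×0.2) and vice versa. Each population's profile is
renormalized to the same expected library size so depth does not encode
identity. Marker structure combines a handful of named field markers per
population (e.g. VCAN/NFIA, TOP2A/MKI67, GFAP/CD44, AQP4/SPARCL1, TH/NR4A2/
SLC6A3…) with `n_extra_markers = 30` synthetic program genes per population:
real subpopulations differ in tens of co-regulated genes, and six named
genes alone would be an unrealistically weak signal against ~2,500
background genes. Mitochondrial features (13, class `Mito`) are pinned to
0.5% of the library so most cells pass the 1% QC rule, as in a clean
nuclei prep.

**Populations and conversion.** Cell identity starts from five cluster
proportions at D0 (defaults 0.30/0.20/0.24/0.10/0.16, summing to 1) and a
per-timepoint neuronal fraction (D2: 0.21 rising to D21: 0.76). Every
post-D0 cell carries a glial cluster of origin; a cell converts with
probability `rate(timepoint) × cluster_conversion_effect[origin]`. With all
effects at 1 (the default) conversion is exchangeable across starting
clusters — the null the clonal model should not reject. Conversion is drawn
while the truth table is built, *before* counts, so expression always
reflects converted identity. Optionally conversion probability can instead
be tied to the cell's transgene group (none / partial / all three) to plant
a dose–outcome dependence.

**Transgenes.** Integrated copies are Poisson(MOI) per factor (default MOI
1.5, within the experimental 1–2 per vector). Observed UMIs are a binomial
thinning (capture 0.3) of `copies × 30` molecules, so zero copies give zero
UMIs exactly, and full capture guarantees detection — the limit cases the
calling rule is tested against. Transgene features carry class `Transgene`
and are excluded from normalization totals and HVG selection so viral load
cannot distort clustering.

**Clones and barcode reads.** `n_clones = 66` clones receive long-tailed
geometric weights (ratio 0.93), producing a few large clones and many small
ones. Clones are *not* forced cluster-pure at D0; post-D0 members inherit
an origin cluster from the clone's empirical D0 composition, which is
exactly the generative model behind the compositional regression. Each
barcoded cell yields reads with probability 0.6; reads follow the 10x v3
layout (R1 = 16-nt cell barcode + 12-nt UMI) and R2 carries
`prefix + GTCGTGA + barcode(20) + CTCGAC + libraryID(12) + padding` with
per-base substitution errors (default 0.005). Decoy reads without the motif
are mixed in at 40% of the stream, standing in for off-target library
material. Clone barcodes are drawn uniformly from 20-mer space rather than
materializing the ~10⁶-barcode library; collision probability at tens of
clones is negligible.

**Determinism.** One seed fans out through SHA-256-derived named substreams
(`_rng.substream`), so stages are independent and reordering one does not
change another's draws; identical configurations give byte-identical MTX
and FASTQ output (gzip written with fixed mtime).

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, UMI collisions, barcode silencing, or library-ID multiplexing.
Passing tests therefore demonstrate correctness of the analysis logic under
a clean generative model, not robustness to those artifacts; the
batch-integration step is a documented identity hook.

## Analysis stages

**QC.** Cells kept with detected genes in the inclusive window
[1,000, 12,000] and mitochondrial fraction ≤ 0.01 (strictly-above
excluded). Transgenes count toward neither rule. Doublet removal is out of
scope; the report carries a placeholder field.

**Normalization.** Counts scaled to 10,000 per cell (total over
endogenous features only) then log1p. Cells with zero endogenous totals are
dropped with a warning.

**HVG selection (vst scheme).** A degree-2 polynomial in log10 space fits
the mean–variance trend of raw counts (standing in for a loess; adequate
for the smooth synthetic trend), counts are standardized by the fitted SD,
clipped at √n, and genes ranked by the variance of the clipped values with
lexicographic tie-breaks — fully deterministic. Default 4,000 genes (fewer
at unit-test scale).

**Clustering.** PCA (25 components) on z-scored, ±10-clipped HVG
expression; exact kNN graph (k = 20, sklearn); Louvain via igraph
`community_multilevel` at resolution 0.3, seeded through Python's `random`
(igraph's RNG source). Labels are renumbered by descending cluster size.
k is the conventional default; the resolution and component count follow
the standard single-cell workflow for this design.

**Annotation.** Each cluster takes the reference marker set with the
highest mean binned-control module score; ties break by listed order and
are logged.

**Module score.** Genes are placed in 24 equal-frequency bins of average
expression; each set gene draws 100 seeded controls from its bin, excluding
set genes whenever the bin offers any alternative (this exclusion makes the
degenerate one-bin example exact; when the set fills a bin the whole bin is
used, which is what makes the all-genes score collapse to ~0). Score =
mean(set) − mean(controls) per cell; invariant to per-cell constant shifts.

**Differential abundance.** Statistic per cluster:
`log2` fold-difference of proportions with 0.5 pseudo-cells added to every
cluster×condition count (keeps the statistic finite for empty cells and
shrinks tiny-count noise). The null shuffles condition labels at fixed
group sizes; the permuted group is always the lexicographically second
condition level so that swapping the roles of A and B reuses identical
permutations — the p-values are exactly invariant and the statistics exactly
negate. p = `(1 + #{|t*| ≥ |t|}) / (n_perm + 1)` (never 0). CIs are
percentile bootstrap; resampling cells within a condition is performed as
the equivalent multinomial draw over clusters. BH across clusters.
Pooling D2–D7 against D0 is a plain cell union.

**Transgene analysis.** TF-positive at ≥1 UMI (fixed threshold, not scaled
by depth). Groups: none / partial (1–2 factors) / all_three; "any TF" is
the union of the latter two for counting, but the Fisher contingency uses
the disjoint all_three vs partial groups. Additional cassettes (shRNA,
rtTA) are reported but excluded from three-factor logic.

**Barcode pipeline.** Extraction is exact-flank regex matching (first match
per read); the library ID is the 12 nt after the 3′ flank (reads too short
keep an empty ID and are counted). UMI counting deduplicates
(cell, barcode, UMI) triples, matching the #UMI convention. Correction is a
directional greedy collapse within each cell: barcodes in descending-count
order (ties lexicographic) merge into the best already-accepted barcode of
*strictly greater* original count within Levenshtein distance 1 (edlib);
equal counts never merge, cells never share state, per-cell UMI totals are
conserved, and the procedure is idempotent — all asserted against an
independent brute-force oracle. Clone identity is the post-correction
canonical barcode; cells take their top-UMI barcode subject to `min_umi`
and an optional purity threshold, with exact ties left unassigned.

**Clonal conversion model.** Clones with ≥1 cell at D0 and ≥1 cell in the
D2–D7 window contribute a D0 cluster composition (simplex) and a post-
window neuron fraction. Weighted least squares without intercept (weights =
post-window cell counts) yields per-cluster conversion rates; equality is
tested with an F contrast on the k−1 pairwise differences. When the
contrast is exactly zero under a zero-residual fit (the degenerate
perfect-agreement case) the test reports p = 1 rather than 0/0. Clusters
never observed at D0 get NA coefficients; fewer clones than clusters is an
error. Mixed-composition clones are handled either by the joint fit
(default) or, for the per-cluster box statistics, by `pure` (only
single-cluster clones) or `weighted` (attribute the clone's conversion to
every cluster it occupies at D0) attribution. Box statistics use type-7
(linear interpolation) quartiles, with points outside [Q1, Q3] counted as
outliers, matching a quartile-range box drawing.

## Problem sizes

Unit tests run at 300–3,500 cells per timepoint with 400–2,500 genes; the
acceptance checks use 3,000 cells per side for the proportion test and
population recovery, 100 clones for rate recovery, and 5,000 cells for
capture-rate estimation. The analysis scripts use 1,000 cells per timepoint
across seven timepoints. These sizes give the statistical procedures
adequate power while keeping any single run in seconds to a couple of
minutes on one CPU.

## Known limitations

- The mean–variance trend is polynomial, not loess; on real data with
  complex trends a loess fit would be preferable.
- The permutation test treats cells as exchangeable units; it is not a
  replicate-aware differential-abundance method.
- Directional greedy collapse approximates message-passing style barcode
  clustering; the oracle equivalence holds for the directional rule as
  defined, not for other collapse schemes.
- Conversion modeling assumes the post-window composition of a clone
  reflects its D0 composition (no differential proliferation).
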