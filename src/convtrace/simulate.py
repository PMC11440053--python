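"""Ground-truthed synthetic data emulating a glia-to-neuron conversion experiment.

The generator produces everything the downstream analysis consumes:

* a cells x features UMI count matrix with five glial progenitor (OPC)
  subpopulations at the starting timepoint and a neuronal population that
  grows across later timepoints, each population carrying its own elevated
  marker genes on a shared negative-binomial background;
* per-cell transgene copy numbers (Poisson at the configured multiplicity
  of infection) for the three conversion factors, observed as
  binomially-thinned transgene UMIs;
* clone-structured lineage-barcode read pairs in FASTQ form, where each
  clone shares a random 20-nt barcode embedded in the cassette
  ``<flank5><barcode 20nt><flank3><library id 12nt>`` with per-base
  substitution errors and a configurable fraction of motif-free decoy reads;
* a ground-truth table (separate file, never read by analysis stages).

All randomness fans out from ``SimConfig.seed`` through named substreams, so
identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as ctio
from ._rng import substream

NT = np.array(list("ACGT"))

DEFAULT_TIMEPOINTS = ("D0", "D2", "D3", "D5", "D7", "D14", "D21")

DEFAULT_CLUSTER_PROPORTIONS = {
    "OPC1": 0.30,
    "OPC2": 0.20,
    "OPC3": 0.24,
    "OPC4": 0.10,
    "OPC5": 0.16,
}

DEFAULT_NEURON_FRACTION = {
    "D0": 0.0,
    "D2": 0.21,
    "D3": 0.30,
    "D5": 0.40,
    "D7": 0.50,
    "D14": 0.65,
    "D21": 0.76,
}

# Marker genes per subpopulation, loosely following the reported glial
# progenitor heterogeneity: early progenitors (OPC1/2), a cycling cluster
# (OPC3), bipotent glia (OPC4) and astrocyte-committed cells (OPC5), plus a
# dopaminergic/neuronal signature for converted cells.
DEFAULT_MARKERS: Dict[str, Sequence[str]] = {
    "OPC1": ("VCAN", "NFIA", "OLIG1", "SOX6", "CSPG4", "EGFR"),
    "OPC2": ("BCAN", "TNR", "DLL3", "SOX8", "GPR17", "PCDH15"),
    "OPC3": ("TOP2A", "MKI67", "CENPF", "ASPM", "TPX2", "CCNB1"),
    "OPC4": ("GFAP", "SLC1A3", "CD44", "S100B", "ID3", "VIM"),
    "OPC5": ("AQP4", "SPARCL1", "SOX9", "ALDH1L1", "FGFR3", "CLU"),
    "neuron": (
        "TH", "SYT1", "MAPT", "NR4A2", "SLC18A2", "KCNN3",
        "RET", "KCNJ6", "SLC6A3", "DRD2", "SNAP25", "STMN2",
    ),
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic conversion experiment.

    Defaults reflect the modeled experiment: five OPC subpopulations at D0,
    a neuronal fraction growing to 76% by D21, a multiplicity of infection of
    1-2 per conversion-factor vector, a ~1e6-barcode lineage library with
    20-nt barcodes, and ~60% of cells yielding barcode reads.
    """

    n_cells_per_timepoint: int = 3000
    timepoints: Tuple[str, ...] = DEFAULT_TIMEPOINTS
    cluster_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_PROPORTIONS)
    )
    neuron_fraction_by_timepoint: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NEURON_FRACTION)
    )
    n_genes: int = 2500
    n_mito_genes: int = 13
    marker_spec: Dict[str, Sequence[str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_MARKERS.items()}
    )
    marker_fold: float = 8.0
    # each population differs in its named markers plus this many additional
    # program genes — subpopulations separate on tens of genes, not a handful
    n_extra_markers: int = 30
    marker_base_weight: float = 1.0  # pre-scaling base mean of marker genes
    mean_umi_per_cell: float = 5000.0
    dispersion: float = 2.0  # negative-binomial size parameter
    mito_fraction: float = 0.005

    # transgenes
    tf_names: Tuple[str, ...] = ("Ascl1", "Lmx1a", "Nurr1")
    moi: float = 1.5
    transgene_capture_rate: float = 0.3
    transgene_expression_per_copy: int = 30

    # lineage barcodes
    n_barcodes_library: int = 1_000_000
    barcode_len: int = 20
    flank5: str = "GTCGTGA"
    flank3: str = "CTCGAC"
    library_id: str = "ACGTACGTACGT"
    seq_error_rate: float = 0.005
    barcode_capture_rate: float = 0.6
    decoy_fraction: float = 0.4
    n_clones: int = 66
    clone_fraction: float = 1.0
    clone_decay: float = 0.93  # geometric ratio of clone weights -> long tail
    umis_per_barcoded_cell: float = 4.0
    reads_per_umi: float = 2.0
    r2_length: int = 90

    # conversion model
    cluster_conversion_effect: Dict[str, float] = field(default_factory=dict)
    conversion_by_tf_group: Optional[Dict[str, float]] = None

    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cluster_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"cluster_proportions sum to {total}, expected 1")
        for name, p in self.cluster_proportions.items():
            if p < 0:
                raise ConfigError(f"negative proportion for {name}")
        for tp, f in self.neuron_fraction_by_timepoint.items():
            if not 0 <= f <= 1:
                raise ConfigError(f"neuron fraction for {tp} outside [0,1]")
        for prob_name in (
            "transgene_capture_rate",
            "barcode_capture_rate",
            "decoy_fraction",
            "seq_error_rate",
            "clone_fraction",
        ):
            p = getattr(self, prob_name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{prob_name}={p} outside [0,1]")
        if self.barcode_len != 20:
            raise ConfigError("barcode_len must be 20 (cassette design)")
        if len(self.library_id) != 12:
            raise ConfigError("library_id must be 12 nt")
        if self.n_cells_per_timepoint <= 0 or self.n_genes <= 0:
            raise ConfigError("n_cells_per_timepoint and n_genes must be positive")
        if self.moi < 0 or self.mean_umi_per_cell <= 0 or self.dispersion <= 0:
            raise ConfigError("moi must be >= 0; mean_umi/dispersion must be > 0")
        if not self.cluster_conversion_effect:
            self.cluster_conversion_effect = {
                c: 1.0 for c in self.cluster_proportions
            }

    @property
    def clusters(self) -> Tuple[str, ...]:
        return tuple(self.cluster_proportions)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(d["timepoints"])
        return json.dumps(d, indent=2, default=list)


# ---------------------------------------------------------------------------
# ground truth


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n distinct random k-mers over ACGT."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = NT[rng.integers(0, 4, size=(n - len(out), k))]
        for row in block:
            s = "".join(row)
            if s not in seen:
                seen.add(s)
                out.append(s)
    return np.array(out)


def build_truth(config: SimConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Construct the per-cell ground-truth table.

    Columns: ``timepoint``, ``true_cluster`` (glial cluster of origin),
    ``is_neuron``, ``clone_id`` (NA when the cell carries no lineage
    barcode), and ``copies_<factor>`` for each conversion factor.
    """
    if rng is None:
        rng = substream(config.seed, "truth")
    clusters = np.array(config.clusters)
    probs = np.array([config.cluster_proportions[c] for c in clusters])
    probs = probs / probs.sum()

    n_tp = config.n_cells_per_timepoint
    rows = []
    cell_ids = _random_kmers(rng, n_tp * len(config.timepoints), 16)
    # long-tailed clone weights
    clone_ids = np.array([f"clone{k:03d}" for k in range(config.n_clones)])
    w = config.clone_decay ** np.arange(config.n_clones)
    w = w / w.sum()

    idx = 0
    clone_of_cell: Dict[str, Dict[str, np.ndarray]] = {}
    for tp in config.timepoints:
        ids = cell_ids[idx : idx + n_tp]
        idx += n_tp
        barcoded = rng.random(n_tp) < config.clone_fraction
        clone = np.where(
            barcoded, clone_ids[rng.choice(config.n_clones, size=n_tp, p=w)], None
        )
        clone_of_cell[tp] = {"ids": ids, "clone": clone}
        rows.append(
            pd.DataFrame(
                {
                    "timepoint": tp,
                    "clone_id": clone,
                },
                index=ids,
            )
        )
    truth = pd.concat(rows)
    truth.index.name = "cell"

    # Glial cluster of origin.  D0 cells and clone-free cells draw i.i.d.
    # from the configured proportions; post-D0 clone members descend from the
    # clone's D0 cells, so they inherit a cluster drawn from the clone's
    # empirical D0 composition.
    cluster_col = pd.Series(index=truth.index, dtype=object)
    d0 = config.timepoints[0]
    d0_mask = truth["timepoint"] == d0
    cluster_col[d0_mask] = clusters[rng.choice(len(clusters), size=d0_mask.sum(), p=probs)]

    d0_truth = truth[d0_mask].copy()
    d0_truth["cluster"] = cluster_col[d0_mask]
    clone_d0_clusters = {
        cid: grp["cluster"].to_numpy()
        for cid, grp in d0_truth.dropna(subset=["clone_id"]).groupby("clone_id")
    }
    post_mask = ~d0_mask
    post = truth[post_mask]
    assigned = np.empty(post_mask.sum(), dtype=object)
    for i, (cell, row) in enumerate(post.iterrows()):
        cid = row["clone_id"]
        ancestors = clone_d0_clusters.get(cid) if cid is not None else None
        if ancestors is not None and len(ancestors):
            assigned[i] = ancestors[rng.integers(0, len(ancestors))]
        else:
            assigned[i] = clusters[rng.choice(len(clusters), p=probs)]
    cluster_col[post_mask] = assigned
    truth["true_cluster"] = cluster_col

    # transgene copies (multiplicity of infection per vector)
    for tf in config.tf_names:
        truth[f"copies_{tf}"] = rng.poisson(config.moi, size=len(truth))

    truth["is_neuron"] = False
    truth = simulate_conversion(config, truth, rng=rng)
    return truth


def tf_group(truth_or_calls: pd.DataFrame, prefix: str, tf_names: Sequence[str]) -> pd.Series:
    """Group cells by transgene status: none / partial (1-2 factors) / all_three."""
    pos = pd.concat(
        [(truth_or_calls[f"{prefix}{tf}"] > 0) for tf in tf_names], axis=1
    )
    n_pos = pos.sum(axis=1)
    out = pd.Series("none", index=truth_or_calls.index, dtype=object)
    out[n_pos >= 1] = "partial"
    out[n_pos == len(tf_names)] = "all_three"
    return out


def simulate_conversion(
    config: SimConfig,
    truth: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
    base_rate: Optional[float] = None,
) -> pd.DataFrame:
    """Draw neuronal conversion flags for post-D0 cells.

    Each post-D0 cell converts with probability
    ``rate(timepoint) * cluster_conversion_effect[origin cluster]``, where
    ``rate`` is the configured per-timepoint neuron fraction (or the flat
    ``base_rate`` override).  With all effects equal to 1 conversion is
    exchangeable across the glial clusters of origin — the null model.  When
    ``conversion_by_tf_group`` is configured, conversion probability instead
    depends on the cell's transgene group (none/partial/all_three).
    """
    if rng is None:
        rng = substream(config.seed, "conversion")
    truth = truth.copy()
    d0 = config.timepoints[0]
    post = truth["timepoint"] != d0
    n_post = int(post.sum())
    if n_post == 0:
        return truth

    if config.conversion_by_tf_group is not None:
        groups = tf_group(truth.loc[post], "copies_", config.tf_names)
        p = groups.map(config.conversion_by_tf_group).astype(float).to_numpy()
    else:
        if base_rate is None:
            rate = truth.loc[post, "timepoint"].map(
                config.neuron_fraction_by_timepoint
            ).astype(float)
        else:
            rate = pd.Series(float(base_rate), index=truth.index[post])
        effect = truth.loc[post, "true_cluster"].map(
            config.cluster_conversion_effect
        ).astype(float)
        p = np.clip((rate * effect).to_numpy(), 0.0, 1.0)

    truth.loc[post, "is_neuron"] = rng.random(n_post) < p
    truth.loc[~post, "is_neuron"] = False
    return truth


# ---------------------------------------------------------------------------
# counts


def full_marker_spec(config: SimConfig) -> Dict[str, list]:
    """Named markers plus the per-population synthetic program genes."""
    spec = {k: list(v) for k, v in config.marker_spec.items()}
    for pop in spec:
        spec[pop] += [f"{pop}-mk{i:02d}" for i in range(config.n_extra_markers)]
    return spec


def _feature_table(config: SimConfig) -> pd.DataFrame:
    marker_genes: list[str] = []
    for genes in full_marker_spec(config).values():
        for g in genes:
            if g not in marker_genes:
                marker_genes.append(g)
    n_filler = config.n_genes - len(marker_genes)
    if n_filler < 0:
        raise ConfigError("n_genes smaller than the number of marker genes")
    filler = [f"Gene{i:04d}" for i in range(n_filler)]
    mito = [f"MT-{i+1}" for i in range(config.n_mito_genes)]
    names = marker_genes + filler + mito
    classes = [ctio.GENE_CLASS] * (len(marker_genes) + n_filler) + [
        ctio.MITO_CLASS
    ] * len(mito)
    return pd.DataFrame({"gene_symbol": names, "feature_class": classes}, index=names)


def simulate_counts(
    config: SimConfig,
    truth: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ad.AnnData, pd.DataFrame]:
    """Draw the UMI count matrix given (or building) the ground truth.

    Counts are negative binomial per gene with a per-cell lognormal library
    size factor.  Marker genes are elevated ``marker_fold``-fold in their own
    population; neurons additionally down-weight all glial marker genes.
    Expression profiles are renormalized per population so that library size
    does not encode cell identity.
    """
    if truth is None:
        truth = build_truth(config)
    if rng is None:
        rng = substream(config.seed, "counts")

    features = _feature_table(config)
    genes = features.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    mito_mask = (features["feature_class"] == ctio.MITO_CLASS).to_numpy()
    base = rng.lognormal(mean=np.log(0.5), sigma=1.2, size=n_genes)
    marker_spec = full_marker_spec(config)
    all_markers = sorted({g for genes in marker_spec.values() for g in genes})
    base[[gene_pos[g] for g in all_markers]] = config.marker_base_weight
    # pin mitochondrial content to its target share of the library
    base[mito_mask] = 1.0
    base[~mito_mask] *= (1 - config.mito_fraction) / base[~mito_mask].sum()
    base[mito_mask] *= config.mito_fraction / base[mito_mask].sum()
    base *= config.mean_umi_per_cell

    populations = list(config.clusters) + ["neuron"]
    glial_markers = [
        g for c in config.clusters for g in marker_spec.get(c, ())
    ]
    profiles = np.empty((len(populations), n_genes))
    for pi, pop in enumerate(populations):
        mu = base.copy()
        for g in marker_spec.get(pop, ()):
            mu[gene_pos[g]] *= config.marker_fold
        if pop == "neuron":
            for g in glial_markers:
                mu[gene_pos[g]] *= 0.2
        else:
            for g in marker_spec.get("neuron", ()):
                mu[gene_pos[g]] *= 0.2
        mu *= config.mean_umi_per_cell / mu.sum()
        profiles[pi] = mu

    pop_idx = np.where(
        truth["is_neuron"].to_numpy(),
        len(populations) - 1,
        pd.Categorical(
            truth["true_cluster"], categories=list(config.clusters)
        ).codes,
    )
    size_factor = rng.lognormal(mean=0.0, sigma=0.25, size=len(truth))
    mu = profiles[pop_idx] * size_factor[:, None]
    size = config.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))

    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int32)),
        obs=pd.DataFrame(
            {
                "timepoint": truth["timepoint"].to_numpy(),
                "condition": np.where(
                    truth["timepoint"] == config.timepoints[0], "D0", "ALNRi"
                ),
            },
            index=truth.index,
        ),
        var=features,
    )
    adata.layers["counts"] = adata.X.copy()
    return adata, truth


def simulate_transgenes(
    config: SimConfig,
    adata: ad.AnnData,
    truth: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> ad.AnnData:
    """Append transgene UMI columns driven by the ground-truth copy numbers.

    Per cell and factor, expression is ``copies * transgene_expression_per_copy``
    molecules thinned binomially at the capture rate, so zero copies always
    yield zero UMIs and capture 1 with non-zero expression guarantees
    detection.
    """
    if rng is None:
        rng = substream(config.seed, "transgenes")
    truth = truth.loc[adata.obs_names]
    cols = []
    names = []
    for tf in config.tf_names:
        copies = truth[f"copies_{tf}"].to_numpy()
        expressed = copies * config.transgene_expression_per_copy
        observed = rng.binomial(expressed, config.transgene_capture_rate)
        cols.append(observed)
        names.append(f"tg-{tf}")
    tg = sp.csr_matrix(np.column_stack(cols).astype(np.int32))
    var = pd.concat(
        [
            adata.var,
            pd.DataFrame(
                {"gene_symbol": names, "feature_class": ctio.TRANSGENE_CLASS},
                index=names,
            ),
        ]
    )
    X = sp.hstack([adata.layers["counts"], tg]).tocsr()
    out = ad.AnnData(X=X.copy(), obs=adata.obs.copy(), var=var)
    out.layers["counts"] = X.copy()
    return out


# ---------------------------------------------------------------------------
# barcode reads


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.where(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = letters[letters != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_barcode_reads(
    config: SimConfig,
    truth: pd.DataFrame,
    out_r1: str,
    out_r2: str,
    whitelist_path: str,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, str]:
    """Write the lineage-barcode FASTQ pair and cell-barcode whitelist.

    R1 carries the 16-nt cell barcode followed by a 12-nt UMI; R2 carries a
    random prefix, the ``flank5 + barcode + flank3 + library_id`` cassette and
    random padding.  Each barcoded cell yields reads with probability
    ``barcode_capture_rate``; decoy reads without the motif are mixed in at
    ``decoy_fraction`` of the final read stream.  Returns the clone-to-barcode
    map (ground truth for tests; analysis stages never see it).
    """
    if rng is None:
        rng = substream(config.seed, "barcode_reads")
    clone_ids = sorted({c for c in truth["clone_id"].dropna().unique()})
    barcode_of_clone = dict(
        zip(clone_ids, _random_kmers(rng, len(clone_ids), config.barcode_len))
    )

    reads: list[Tuple[str, str, str]] = []  # (read_id, r1, r2)
    n = 0
    prefix_len = 8
    cassette_len = (
        prefix_len
        + len(config.flank5)
        + config.barcode_len
        + len(config.flank3)
        + len(config.library_id)
    )
    pad_len = max(config.r2_length - cassette_len, 0)

    barcoded = truth.dropna(subset=["clone_id"])
    captured = rng.random(len(barcoded)) < config.barcode_capture_rate
    for (cell, row), cap in zip(barcoded.iterrows(), captured):
        if not cap:
            continue
        vb = barcode_of_clone[row["clone_id"]]
        n_umi = 1 + rng.poisson(max(config.umis_per_barcoded_cell - 1, 0))
        for _ in range(n_umi):
            umi = "".join(NT[rng.integers(0, 4, size=12)])
            n_reads = 1 + rng.poisson(max(config.reads_per_umi - 1, 0))
            for _ in range(n_reads):
                prefix = "".join(NT[rng.integers(0, 4, size=prefix_len)])
                pad = "".join(NT[rng.integers(0, 4, size=pad_len)])
                r2 = (
                    prefix + config.flank5 + vb + config.flank3
                    + config.library_id + pad
                )
                r2 = _mutate(r2, rng, config.seq_error_rate)
                reads.append((f"read{n:07d}", cell + umi, r2))
                n += 1

    # decoy reads lacking the motif
    if config.decoy_fraction > 0 and len(reads) > 0:
        n_decoy = int(round(
            config.decoy_fraction / (1 - config.decoy_fraction) * len(reads)
        ))
        all_cells = truth.index.to_numpy()
        import re

        motif = re.compile(f"{config.flank5}[ACGT]{{{config.barcode_len}}}{config.flank3}")
        for _ in range(n_decoy):
            cell = all_cells[rng.integers(0, len(all_cells))]
            umi = "".join(NT[rng.integers(0, 4, size=12)])
            while True:
                r2 = "".join(NT[rng.integers(0, 4, size=config.r2_length)])
                if not motif.search(r2):
                    break
            reads.append((f"read{n:07d}", cell + umi, r2))
            n += 1

    order = rng.permutation(len(reads))
    os.makedirs(os.path.dirname(os.path.abspath(out_r1)), exist_ok=True)

    import contextlib

    @contextlib.contextmanager
    def _writer(path: str):
        raw = open(path, "wb")
        try:
            if str(path).endswith(".gz"):
                # fixed mtime/name so identical configs give identical bytes
                with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
                    yield gz
            else:
                yield raw
        finally:
            raw.close()

    with _writer(out_r1) as f1, _writer(out_r2) as f2:
        for i in order:
            rid, r1, r2 = reads[i]
            f1.write(f"@{rid}\n{r1}\n+\n{'I' * len(r1)}\n".encode())
            f2.write(f"@{rid}\n{r2}\n+\n{'I' * len(r2)}\n".encode())

    with open(whitelist_path, "w") as fh:
        for cell in truth.index:
            fh.write(f"{cell}\n")
    return barcode_of_clone


# ---------------------------------------------------------------------------
# dataset driver


def simulate_dataset(config: SimConfig, outdir: str) -> Dict[str, str]:
    """Generate the full synthetic dataset under ``outdir``.

    Writes the MTX triplet (with transgene features), per-cell metadata TSV,
    whitelist TSV, barcode FASTQ pair, the ground-truth TSV (separate file,
    for evaluation only) and a JSON echo of the configuration.  Returns the
    paths of everything written.
    """
    os.makedirs(outdir, exist_ok=True)
    truth = build_truth(config)
    adata, truth = simulate_counts(config, truth)
    adata = simulate_transgenes(config, adata, truth)

    mtx_dir = os.path.join(outdir, "counts")
    ctio.write_mtx_dir(adata, mtx_dir)

    paths = {
        "counts": mtx_dir,
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "whitelist": os.path.join(outdir, "whitelist.tsv"),
        "fastq_r1": os.path.join(outdir, "barcodes_R1.fastq.gz"),
        "fastq_r2": os.path.join(outdir, "barcodes_R2.fastq.gz"),
        "ground_truth": os.path.join(outdir, "ground_truth.tsv"),
        "config": os.path.join(outdir, "config.json"),
    }
    meta = adata.obs.reset_index().rename(columns={"index": "cell"})
    meta.to_csv(paths["metadata"], sep="\t", index=False)

    barcode_of_clone = simulate_barcode_reads(
        config, truth, paths["fastq_r1"], paths["fastq_r2"], paths["whitelist"]
    )
    truth_out = truth.reset_index().rename(columns={"index": "cell"})
    truth_out["clone_barcode"] = truth_out["clone_id"].map(barcode_of_clone)
    truth_out.to_csv(paths["ground_truth"], sep="\t", index=False)

    with open(paths["config"], "w") as fh:
        fh.write(config.to_json())
    return paths
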