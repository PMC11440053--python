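"""Generator contracts: determinism, planted structure, closed-form agreement."""

import filecmp
import gzip
import re

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from convtrace import (
    SimConfig,
    build_truth,
    simulate_barcode_reads,
    simulate_conversion,
    simulate_counts,
    simulate_dataset,
    simulate_transgenes,
)
from convtrace.simulate import ConfigError

from conftest import small_sim_config


def binomial_ci99(n: int, p: float) -> tuple[float, float]:
    """Exact binomial 99% central interval for the observed fraction."""
    lo = binom.ppf(0.005, n, p) / n
    hi = binom.ppf(0.995, n, p) / n
    return lo, hi


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            small_sim_config(cluster_proportions={"A": 0.5, "B": 0.6})

    def test_probabilities_bounded(self):
        with pytest.raises(ConfigError):
            small_sim_config(barcode_capture_rate=1.5)

    def test_cassette_geometry_fixed(self):
        with pytest.raises(ConfigError):
            small_sim_config(barcode_len=19)
        with pytest.raises(ConfigError):
            small_sim_config(library_id="TOOSHORT")


def test_identical_seed_gives_byte_identical_outputs(tmp_path):
    cfg = small_sim_config(n_cells_per_timepoint=100, n_clones=8)
    p1 = simulate_dataset(cfg, str(tmp_path / "run1"))
    p2 = simulate_dataset(cfg, str(tmp_path / "run2"))
    for key in ("fastq_r1", "fastq_r2"):
        assert filecmp.cmp(p1[key], p2[key], shallow=False), key
    assert filecmp.cmp(
        f"{p1['counts']}/matrix.mtx", f"{p2['counts']}/matrix.mtx", shallow=False
    )
    t1 = pd.read_csv(p1["ground_truth"], sep="\t")
    t2 = pd.read_csv(p2["ground_truth"], sep="\t")
    pd.testing.assert_frame_equal(t1, t2)


def test_zero_neuron_fraction_means_no_neurons():
    cfg = small_sim_config(
        neuron_fraction_by_timepoint={"D0": 0.0, "D2": 0.0, "D7": 0.0}
    )
    truth = build_truth(cfg)
    assert not truth["is_neuron"].any()


def test_cell_counts_conserved_per_timepoint(small_dataset):
    cfg, adata, truth = small_dataset
    counts = truth.groupby("timepoint").size()
    assert (counts == cfg.n_cells_per_timepoint).all()
    assert adata.n_obs == cfg.n_cells_per_timepoint * len(cfg.timepoints)
    assert truth.index.is_unique


def test_d0_cluster_fractions_within_binomial_ci():
    props = {"OPC1": 0.30, "OPC2": 0.20, "OPC3": 0.24, "OPC4": 0.10, "OPC5": 0.16}
    cfg = small_sim_config(
        n_cells_per_timepoint=3000,
        timepoints=("D0",),
        neuron_fraction_by_timepoint={"D0": 0.0},
        cluster_proportions=props,
        seed=21,
    )
    truth = build_truth(cfg)
    observed = truth["true_cluster"].value_counts(normalize=True)
    for cl, p in props.items():
        lo, hi = binomial_ci99(3000, p)
        assert lo <= observed[cl] <= hi, (cl, observed[cl])


class TestTransgenes:
    def test_moi_zero_means_zero_umis(self):
        cfg = small_sim_config(moi=0.0)
        adata, truth = simulate_counts(cfg)
        adata = simulate_transgenes(cfg, adata, truth)
        tg = adata[:, [f"tg-{t}" for t in cfg.tf_names]].layers["counts"]
        assert tg.sum() == 0

    def test_triple_transduction_matches_poisson_closed_form(self):
        cfg = small_sim_config(
            n_cells_per_timepoint=10000, timepoints=("D0",),
            neuron_fraction_by_timepoint={"D0": 0.0}, moi=1.5, seed=13,
        )
        truth = build_truth(cfg)
        triple = (
            (truth[[f"copies_{t}" for t in cfg.tf_names]] > 0).all(axis=1).mean()
        )
        expected = (1 - np.exp(-cfg.moi)) ** 3
        lo, hi = binomial_ci99(10000, expected)
        assert lo <= triple <= hi

    def test_full_capture_detects_every_transduced_cell(self):
        cfg = small_sim_config(transgene_capture_rate=1.0)
        adata, truth = simulate_counts(cfg)
        adata = simulate_transgenes(cfg, adata, truth)
        for tf in cfg.tf_names:
            umis = np.asarray(
                adata[:, f"tg-{tf}"].layers["counts"].todense()
            ).ravel()
            has_copy = truth.loc[adata.obs_names, f"copies_{tf}"] > 0
            assert (umis[has_copy.to_numpy()] >= 1).all()
            assert (umis[~has_copy.to_numpy()] == 0).all()


class TestBarcodeReads:
    def _reads(self, path):
        with gzip.open(path, "rt") as fh:
            lines = fh.read().splitlines()
        return lines[1::4]

    def test_error_free_reads_all_match_motif(self, tmp_path):
        cfg = small_sim_config(seq_error_rate=0.0, decoy_fraction=0.0)
        truth = build_truth(cfg)
        simulate_barcode_reads(
            cfg, truth, str(tmp_path / "r1.fastq.gz"), str(tmp_path / "r2.fastq.gz"),
            str(tmp_path / "wl.tsv"),
        )
        motif = re.compile(f"{cfg.flank5}[ACGT]{{20}}{cfg.flank3}")
        seqs = self._reads(tmp_path / "r2.fastq.gz")
        assert seqs and all(motif.search(s) for s in seqs)

    def test_clone_members_share_identical_barcode_without_errors(self, tmp_path):
        cfg = small_sim_config(seq_error_rate=0.0, decoy_fraction=0.0,
                               barcode_capture_rate=1.0)
        truth = build_truth(cfg)
        barcode_of_clone = simulate_barcode_reads(
            cfg, truth, str(tmp_path / "r1.fastq.gz"), str(tmp_path / "r2.fastq.gz"),
            str(tmp_path / "wl.tsv"),
        )
        motif = re.compile(f"{cfg.flank5}([ACGT]{{20}}){cfg.flank3}")
        r1 = self._reads(tmp_path / "r1.fastq.gz")
        r2 = self._reads(tmp_path / "r2.fastq.gz")
        truth_bc = truth["clone_id"].map(barcode_of_clone)
        for s1, s2 in zip(r1, r2):
            cell = s1[:16]
            assert motif.search(s2).group(1) == truth_bc[cell]

    def test_capture_rate_fraction_of_cells_with_reads(self, tmp_path):
        cfg = small_sim_config(
            n_cells_per_timepoint=2500, timepoints=("D0", "D2"),
            neuron_fraction_by_timepoint={"D0": 0.0, "D2": 0.3},
            barcode_capture_rate=0.6, decoy_fraction=0.0, seed=5,
            umis_per_barcoded_cell=1.0, reads_per_umi=1.0,
        )
        truth = build_truth(cfg)
        simulate_barcode_reads(
            cfg, truth, str(tmp_path / "r1.fastq.gz"), str(tmp_path / "r2.fastq.gz"),
            str(tmp_path / "wl.tsv"),
        )
        cells_with_reads = {s[:16] for s in self._reads(tmp_path / "r1.fastq.gz")}
        frac = len(cells_with_reads) / len(truth)
        lo, hi = binomial_ci99(len(truth), 0.6)
        assert lo <= frac <= hi

    def test_whitelist_lists_every_cell(self, tmp_path):
        cfg = small_sim_config(n_cells_per_timepoint=80, n_clones=5)
        truth = build_truth(cfg)
        simulate_barcode_reads(
            cfg, truth, str(tmp_path / "r1.fastq.gz"), str(tmp_path / "r2.fastq.gz"),
            str(tmp_path / "wl.tsv"),
        )
        wl = {line.strip() for line in open(tmp_path / "wl.tsv")}
        assert wl == set(truth.index)


class TestConversion:
    def test_base_rate_one_converts_every_post_cell(self):
        cfg = small_sim_config()
        truth = build_truth(cfg)
        truth = simulate_conversion(cfg, truth, base_rate=1.0)
        post = truth["timepoint"] != "D0"
        assert truth.loc[post, "is_neuron"].all()
        assert not truth.loc[~post, "is_neuron"].any()

    def test_null_effects_give_exchangeable_conversion(self):
        # under equal effects, per-cluster conversion rates agree within
        # binomial sampling error
        cfg = small_sim_config(
            n_cells_per_timepoint=4000, timepoints=("D0", "D2"),
            neuron_fraction_by_timepoint={"D0": 0.0, "D2": 0.5}, seed=3,
        )
        truth = build_truth(cfg)
        post = truth[truth["timepoint"] == "D2"]
        rates = post.groupby("true_cluster")["is_neuron"].mean()
        for cl, r in rates.items():
            n = (post["true_cluster"] == cl).sum()
            lo, hi = binomial_ci99(int(n), 0.5)
            assert lo <= r <= hi, (cl, r)

    def test_elevated_effect_raises_cluster_rate(self):
        cfg = small_sim_config(
            n_cells_per_timepoint=3000, timepoints=("D0", "D2"),
            neuron_fraction_by_timepoint={"D0": 0.0, "D2": 0.3},
            cluster_conversion_effect={
                "OPC1": 2.0, "OPC2": 1.0, "OPC3": 1.0, "OPC4": 1.0, "OPC5": 1.0
            },
            seed=9,
        )
        truth = build_truth(cfg)
        post = truth[truth["timepoint"] == "D2"]
        rates = post.groupby("true_cluster")["is_neuron"].mean()
        assert rates["OPC1"] > rates.drop("OPC1").max() + 0.1
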