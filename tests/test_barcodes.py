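"""Barcode extraction, directional ED-1 collapse (with oracle), clone calling."""

import numpy as np
import pandas as pd
import pytest

from convtrace import (
    assign_clones,
    barcode_detection_rate,
    build_truth,
    clone_summary,
    correct_barcodes,
    count_matrix,
    extract_barcodes,
    filter_whitelist,
    run_barcode_pipeline,
    simulate_barcode_reads,
)
from convtrace.barcodes import clone_table
from conftest import small_sim_config

NT = "ACGT"


def write_fastq(path, reads):
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def levenshtein(a, b):
    """Plain DP edit distance (oracle, independent of edlib)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def oracle_collapse(barcode_counts, max_dist=1):
    """Naive directional collapse within one cell: walk barcodes in
    descending-count order (ties lexicographic) and fold each into the first
    accepted barcode of strictly greater original count within edit distance
    max_dist."""
    order = sorted(barcode_counts, key=lambda b: (-barcode_counts[b], b))
    canonical_of = {}
    accepted = []
    for bc in order:
        target = None
        for acc in accepted:
            if barcode_counts[acc] > barcode_counts[bc] and (
                levenshtein(acc, bc) <= max_dist
            ):
                target = acc
                break
        if target is None:
            accepted.append(bc)
            canonical_of[bc] = bc
        else:
            canonical_of[bc] = target
    totals = {}
    for bc, cnt in barcode_counts.items():
        totals[canonical_of[bc]] = totals.get(canonical_of[bc], 0) + cnt
    return totals


class TestExtraction:
    def test_constructed_read_parses_layout(self, tmp_path):
        r2 = "AC" + "GTCGTGA" + "A" * 20 + "CTCGAC" + "T" * 12
        r1 = "C" * 16 + "G" * 12
        write_fastq(tmp_path / "r1.fq", [("r0", r1)])
        write_fastq(tmp_path / "r2.fq", [("r0", r2)])
        rec, stats = extract_barcodes(str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"))
        assert stats.n_matched == 1
        row = rec.iloc[0]
        assert row["viral_barcode"] == "A" * 20
        assert row["library_id"] == "T" * 12
        assert row["cell_barcode"] == "C" * 16
        assert row["umi"] == "G" * 12

    def test_motif_free_read_skipped_and_counted(self, tmp_path):
        write_fastq(tmp_path / "r1.fq", [("r0", "A" * 28)])
        write_fastq(tmp_path / "r2.fq", [("r0", "T" * 60)])
        rec, stats = extract_barcodes(str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"))
        assert len(rec) == 0
        assert stats.n_skipped == 1

    def test_short_library_id_kept_empty_and_counted(self, tmp_path):
        r2 = "GTCGTGA" + "G" * 20 + "CTCGAC" + "TTT"  # only 3 nt after flank3
        write_fastq(tmp_path / "r1.fq", [("r0", "A" * 28)])
        write_fastq(tmp_path / "r2.fq", [("r0", r2)])
        rec, stats = extract_barcodes(str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"))
        assert stats.n_short_library_id == 1
        assert rec.iloc[0]["library_id"] == ""

    def test_unpaired_fastq_errors_with_index(self, tmp_path):
        write_fastq(tmp_path / "r1.fq", [("r0", "A" * 28), ("r1", "A" * 28)])
        write_fastq(tmp_path / "r2.fq", [("r0", "T" * 60)])
        with pytest.raises(ValueError, match="index 1"):
            extract_barcodes(str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"))

    def test_known_mixture_yields_exact_record_count(self, tmp_path):
        rng = np.random.default_rng(0)
        reads1, reads2 = [], []
        for i in range(1000):
            reads1.append((f"r{i}", "".join(rng.choice(list(NT), 28))))
            if i < 600:
                bc = "".join(rng.choice(list(NT), 20))
                reads2.append((f"r{i}", "GTCGTGA" + bc + "CTCGAC" + "A" * 12))
            else:
                reads2.append((f"r{i}", "T" * 60))
        write_fastq(tmp_path / "r1.fq", reads1)
        write_fastq(tmp_path / "r2.fq", reads2)
        rec, stats = extract_barcodes(str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"))
        assert stats.n_matched == len(rec) == 600
        assert stats.n_skipped == 400

    def test_error_free_simulation_recovered_exactly(self, tmp_path):
        cfg = small_sim_config(seq_error_rate=0.0, decoy_fraction=0.0)
        truth = build_truth(cfg)
        bc_of_clone = simulate_barcode_reads(
            cfg, truth, str(tmp_path / "r1.fastq.gz"),
            str(tmp_path / "r2.fastq.gz"), str(tmp_path / "wl.tsv"),
        )
        rec, stats = extract_barcodes(
            str(tmp_path / "r1.fastq.gz"), str(tmp_path / "r2.fastq.gz")
        )
        assert stats.n_skipped == 0
        truth_bc = truth["clone_id"].map(bc_of_clone)
        assert (
            rec["viral_barcode"].to_numpy()
            == truth_bc.loc[rec["cell_barcode"]].to_numpy()
        ).all()
        assert (rec["library_id"] == cfg.library_id).all()


class TestCorrection:
    def _mat(self, cell_barcode_counts):
        rows = [
            {"cell_barcode": cell, "viral_barcode": bc, "umis": cnt}
            for cell, bcs in cell_barcode_counts.items()
            for bc, cnt in bcs.items()
        ]
        return pd.DataFrame(rows)

    def test_minor_variant_absorbed_into_major(self):
        b1 = "A" * 20
        b2 = "C" + "A" * 19  # one substitution away
        mat = self._mat({"cell1": {b1: 100, b2: 2}})
        out, log = correct_barcodes(mat)
        assert len(out) == 1
        assert out.iloc[0]["viral_barcode"] == b1
        assert out.iloc[0]["umis"] == 102
        assert len(log) == 1

    def test_distance_two_barcodes_untouched(self):
        mat = self._mat({"cell1": {"A" * 20: 100, "CC" + "A" * 18: 2}})
        out, log = correct_barcodes(mat)
        assert len(out) == 2
        assert len(log) == 0

    def test_equal_counts_not_merged(self):
        # directional rule requires strictly greater count
        mat = self._mat({"cell1": {"A" * 20: 5, "C" + "A" * 19: 5}})
        out, _ = correct_barcodes(mat)
        assert len(out) == 2

    def test_cells_never_share_state(self):
        b1, b2 = "A" * 20, "C" + "A" * 19
        mat = self._mat({"x": {b1: 100}, "y": {b2: 1}})
        out, log = correct_barcodes(mat)
        assert len(out) == 2 and len(log) == 0

    def test_umi_totals_conserved_and_idempotent(self):
        rng = np.random.default_rng(1)
        mat = self._random_matrix(rng, n_cells=20, max_bcs=15)
        out, _ = correct_barcodes(mat)
        before = mat.groupby("cell_barcode")["umis"].sum()
        after = out.groupby("cell_barcode")["umis"].sum()
        pd.testing.assert_series_equal(before, after)
        out2, log2 = correct_barcodes(out)
        assert len(log2) == 0
        pd.testing.assert_frame_equal(
            out.sort_values(["cell_barcode", "viral_barcode"]).reset_index(drop=True),
            out2.sort_values(["cell_barcode", "viral_barcode"]).reset_index(drop=True),
        )

    def _random_matrix(self, rng, n_cells=10, max_bcs=50, k=8):
        # barcodes drawn from a small mutational neighbourhood so that
        # distance-1 pairs are common
        seeds = ["".join(rng.choice(list(NT), k)) for _ in range(4)]
        rows = []
        for c in range(n_cells):
            n_bc = rng.integers(1, max_bcs + 1)
            seen = {}
            for _ in range(n_bc):
                base = list(seeds[rng.integers(0, len(seeds))])
                for _ in range(rng.integers(0, 3)):
                    base[rng.integers(0, k)] = NT[rng.integers(0, 4)]
                seen["".join(base)] = int(rng.integers(1, 200))
            for bc, cnt in seen.items():
                rows.append(
                    {"cell_barcode": f"cell{c}", "viral_barcode": bc, "umis": cnt}
                )
        return pd.DataFrame(rows)

    def test_matches_brute_force_oracle_on_random_cells(self):
        rng = np.random.default_rng(12)
        for rep in range(10):
            mat = self._random_matrix(rng, n_cells=5, max_bcs=50)
            out, _ = correct_barcodes(mat)
            for cell, grp in mat.groupby("cell_barcode"):
                counts = dict(zip(grp["viral_barcode"], grp["umis"]))
                expected = oracle_collapse(counts)
                got = dict(
                    zip(
                        out[out["cell_barcode"] == cell]["viral_barcode"],
                        out[out["cell_barcode"] == cell]["umis"],
                    )
                )
                assert got == expected, (rep, cell)


from hypothesis import given, settings
from hypothesis import strategies as st

barcode_st = st.text(alphabet="ACGT", min_size=6, max_size=6)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.dictionaries(
        st.tuples(st.sampled_from(["cellA", "cellB"]), barcode_st),
        st.integers(min_value=1, max_value=50),
        min_size=1,
        max_size=25,
    )
)
def test_correction_invariants_hold_for_arbitrary_matrices(counts):
    """UMI conservation, idempotence, and cell isolation for any input."""
    mat = pd.DataFrame(
        [
            {"cell_barcode": cell, "viral_barcode": bc, "umis": c}
            for (cell, bc), c in counts.items()
        ]
    )
    out, log = correct_barcodes(mat)
    # per-cell UMI totals conserved
    pd.testing.assert_series_equal(
        mat.groupby("cell_barcode")["umis"].sum(),
        out.groupby("cell_barcode")["umis"].sum(),
    )
    # idempotent
    out2, log2 = correct_barcodes(out)
    assert len(log2) == 0
    # merges never cross cells
    assert (log["cell_barcode"].isin(mat["cell_barcode"])).all()
    for cell, grp in out.groupby("cell_barcode"):
        original = {bc for (c, bc) in counts if c == cell}
        assert set(grp["viral_barcode"]) <= original


class TestWhitelistAndClones:
    def test_whitelist_passthrough_and_removal(self):
        mat = pd.DataFrame(
            {
                "cell_barcode": ["aa", "bb", "cc"],
                "viral_barcode": ["A" * 20] * 3,
                "umis": [3, 2, 1],
            }
        )
        out, report = filter_whitelist(mat, ["aa", "bb", "cc"])
        assert len(out) == 3 and report["removed_not_whitelisted"] == 0
        out, report = filter_whitelist(mat, ["aa"], retained_cells=["aa"])
        assert list(out["cell_barcode"]) == ["aa"]
        assert report["removed_not_whitelisted"] == 2

    def test_empty_intersection_errors(self):
        mat = pd.DataFrame(
            {"cell_barcode": ["aa"], "viral_barcode": ["A" * 20], "umis": [1]}
        )
        with pytest.raises(ValueError):
            filter_whitelist(mat, ["zz"])

    def test_single_barcode_cell_assigned_and_tie_unassigned(self):
        mat = pd.DataFrame(
            {
                "cell_barcode": ["solo", "tied", "tied"],
                "viral_barcode": ["A" * 20, "C" * 20, "G" * 20],
                "umis": [4, 3, 3],
            }
        )
        res = assign_clones(mat).set_index("cell_barcode")
        assert res.loc["solo", "assigned"]
        assert not res.loc["tied", "assigned"]
        assert res.loc["tied", "tie"]

    def test_min_umi_and_purity_thresholds(self):
        mat = pd.DataFrame(
            {
                "cell_barcode": ["lo", "mixed", "mixed"],
                "viral_barcode": ["A" * 20, "C" * 20, "G" * 20],
                "umis": [1, 5, 4],
            }
        )
        res = assign_clones(mat, min_umi=2).set_index("cell_barcode")
        assert not res.loc["lo", "assigned"]
        res = assign_clones(mat, purity=0.8).set_index("cell_barcode")
        assert not res.loc["mixed", "assigned"]

    def test_detection_rate_is_one_when_all_assigned(self):
        mat = pd.DataFrame(
            {
                "cell_barcode": ["a", "b"],
                "viral_barcode": ["A" * 20, "C" * 20],
                "umis": [2, 3],
            }
        )
        res = assign_clones(mat)
        det = barcode_detection_rate(res, ["a", "b"])
        assert det.iloc[0]["rate"] == 1.0

    def test_clone_summary_shapes_and_flags(self):
        clones = pd.DataFrame(
            {
                "clone_id": ["X"] * 5 + ["Y"] * 2,
                "cluster": ["neuron"] * 5 + ["OPC1", "neuron"],
                "timepoint": ["D2"] * 5 + ["D0", "D7"],
            }
        )
        summary = clone_summary(clones).set_index("clone_id")
        assert summary.loc["X", "size"] == 5
        assert summary.loc["X", "n_cell_types"] == 1
        assert not summary.loc["X", "spans_conversion"]
        assert summary.loc["Y", "spans_conversion"]


def test_full_pipeline_recovers_planted_clones(tmp_path):
    """With realistic error rates, >=95% of assigned cells get their true clone
    and the detection rate matches the configured capture probability."""
    cfg = small_sim_config(
        n_cells_per_timepoint=800, timepoints=("D0", "D2"),
        n_clones=66, seq_error_rate=0.005, barcode_capture_rate=0.6, seed=29,
    )
    truth = build_truth(cfg)
    bc_of_clone = simulate_barcode_reads(
        cfg, truth, str(tmp_path / "r1.fastq.gz"), str(tmp_path / "r2.fastq.gz"),
        str(tmp_path / "wl.tsv"),
    )
    res = run_barcode_pipeline(
        str(tmp_path / "r1.fastq.gz"), str(tmp_path / "r2.fastq.gz"),
        str(tmp_path / "wl.tsv"),
    )
    assigned = res["assignments"].query("assigned").set_index("cell_barcode")
    truth_bc = truth["clone_id"].map(bc_of_clone)
    correct = assigned["clone_id"] == truth_bc.loc[assigned.index]
    assert correct.mean() >= 0.95
    det = barcode_detection_rate(res["assignments"], truth.index)
    assert det.iloc[0]["ci_lower"] <= 0.6 <= det.iloc[0]["ci_upper"]
    # clone membership table joins metadata without losing cells
    meta = truth[["timepoint", "true_cluster"]].rename(
        columns={"true_cluster": "cluster"}
    )
    joined = clone_table(res["assignments"], meta)
    assert len(joined) == len(assigned)
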