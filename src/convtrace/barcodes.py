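"""Lineage-barcode extraction, error correction and clone assignment.

Reads whose R2 matches the cassette motif ``flank5 + [ACGT]{20} + flank3``
yield a record carrying the 10x cell barcode (R1[0:16]), the UMI (R1[16:28]),
the 20-nt viral barcode between the flanks and the 12-nt library ID
immediately after the 3' flank.  Records are deduplicated to distinct
(cell, barcode, UMI) molecules, error-corrected per cell by directional
edit-distance-1 collapse, filtered against the cell whitelist, and turned
into a clone table keyed by the canonical barcode.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd
from scipy.stats import beta

from .io import read_fastq_pair

DEFAULT_FLANK5 = "GTCGTGA"
DEFAULT_FLANK3 = "CTCGAC"


@dataclass
class ExtractionStats:
    n_reads: int = 0
    n_matched: int = 0
    n_skipped: int = 0
    n_short_library_id: int = 0


def extract_barcodes(
    fastq_r1: str,
    fastq_r2: str,
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
    barcode_len: int = 20,
    library_id_len: int = 12,
) -> Tuple[pd.DataFrame, ExtractionStats]:
    """Extract barcode records from a paired FASTQ.

    Returns a DataFrame with columns read_id, cell_barcode, umi,
    viral_barcode, library_id (first motif match per read; non-matching
    reads are counted and skipped), plus extraction statistics.  Reads too
    short for the library ID keep an empty string there and are counted.
    """
    motif = re.compile(
        re.escape(flank5) + f"([ACGT]{{{barcode_len}}})" + re.escape(flank3)
    )
    rows = []
    stats = ExtractionStats()
    for read_id, r1, r2 in read_fastq_pair(fastq_r1, fastq_r2):
        stats.n_reads += 1
        m = motif.search(r2)
        if m is None:
            stats.n_skipped += 1
            continue
        lib = r2[m.end() : m.end() + library_id_len]
        if len(lib) < library_id_len:
            stats.n_short_library_id += 1
            lib = ""
        rows.append(
            {
                "read_id": read_id,
                "cell_barcode": r1[:16],
                "umi": r1[16:28],
                "viral_barcode": m.group(1),
                "library_id": lib,
            }
        )
        stats.n_matched += 1
    records = pd.DataFrame(
        rows,
        columns=["read_id", "cell_barcode", "umi", "viral_barcode", "library_id"],
    )
    return records, stats


def count_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Distinct-UMI counts per (cell barcode, viral barcode).

    Reads are deduplicated by (cell, viral barcode, UMI) so PCR copies of one
    molecule count once.
    """
    dedup = records.drop_duplicates(["cell_barcode", "viral_barcode", "umi"])
    out = (
        dedup.groupby(["cell_barcode", "viral_barcode"], sort=True)
        .size()
        .rename("umis")
        .reset_index()
    )
    return out


def _within(a: str, b: str, max_dist: int) -> bool:
    return edlib.align(a, b, task="distance", k=max_dist)["editDistance"] != -1


def correct_barcodes(
    matrix: pd.DataFrame, max_dist: int = 1
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Directional edit-distance collapse of viral barcodes within each cell.

    Barcodes are processed in descending-count order (ties by lexicographic
    barcode); each barcode merges into the best already-accepted barcode of
    strictly greater original count within Levenshtein distance
    ``max_dist``, and its UMIs are added to that canonical barcode.  Cells
    never share state, so barcodes in different cells are never merged.
    Returns the corrected matrix and a merge log.
    """
    merged_rows = []
    log_rows = []
    for cell, grp in matrix.groupby("cell_barcode", sort=True):
        ordered = grp.sort_values(
            ["umis", "viral_barcode"], ascending=[False, True]
        )
        canon: list[Tuple[str, int]] = []  # (barcode, original count)
        totals: Dict[str, int] = {}
        for bc, cnt in zip(ordered["viral_barcode"], ordered["umis"]):
            target = None
            for cbc, ccnt in canon:  # descending original count
                if ccnt > cnt and _within(bc, cbc, max_dist):
                    target = cbc
                    break
            if target is None:
                canon.append((bc, int(cnt)))
                totals[bc] = totals.get(bc, 0) + int(cnt)
            else:
                totals[target] += int(cnt)
                log_rows.append(
                    {
                        "cell_barcode": cell,
                        "merged_barcode": bc,
                        "into_barcode": target,
                        "umis_moved": int(cnt),
                    }
                )
        for bc, _ in canon:
            merged_rows.append(
                {"cell_barcode": cell, "viral_barcode": bc, "umis": totals[bc]}
            )
    corrected = pd.DataFrame(
        merged_rows, columns=["cell_barcode", "viral_barcode", "umis"]
    )
    log = pd.DataFrame(
        log_rows,
        columns=["cell_barcode", "merged_barcode", "into_barcode", "umis_moved"],
    )
    return corrected, log


def filter_whitelist(
    matrix: pd.DataFrame,
    whitelist: Iterable[str],
    retained_cells: Iterable[str] | None = None,
) -> Tuple[pd.DataFrame, dict]:
    """Restrict the matrix to whitelisted, QC-retained cell barcodes."""
    whitelist = set(whitelist)
    in_wl = matrix["cell_barcode"].isin(whitelist)
    report = {"removed_not_whitelisted": int((~in_wl).sum())}
    out = matrix[in_wl]
    if retained_cells is not None:
        retained = set(retained_cells)
        in_ret = out["cell_barcode"].isin(retained)
        report["removed_not_retained"] = int((~in_ret).sum())
        out = out[in_ret]
    else:
        report["removed_not_retained"] = 0
    if len(out) == 0:
        raise ValueError("no barcode record survives whitelist/retention filtering")
    return out.reset_index(drop=True), report


def assign_clones(
    matrix: pd.DataFrame, min_umi: int = 1, purity: float = 0.0
) -> pd.DataFrame:
    """Assign each cell its top-UMI viral barcode.

    A cell is assigned when the top barcode has at least ``min_umi`` UMIs and
    at least ``purity`` of the cell's barcode UMIs; an exact tie for the top
    leaves the cell unassigned with a flag.  Cells sharing an assigned
    barcode form a clone.
    """
    rows = []
    for cell, grp in matrix.groupby("cell_barcode", sort=True):
        ordered = grp.sort_values(["umis", "viral_barcode"], ascending=[False, True])
        top = ordered.iloc[0]
        total = int(grp["umis"].sum())
        tie = len(ordered) > 1 and int(ordered.iloc[1]["umis"]) == int(top["umis"])
        ok = (
            not tie
            and int(top["umis"]) >= min_umi
            and (total == 0 or top["umis"] / total >= purity)
        )
        rows.append(
            {
                "cell_barcode": cell,
                "clone_id": top["viral_barcode"] if ok else None,
                "top_umis": int(top["umis"]),
                "total_umis": total,
                "assigned": bool(ok),
                "tie": bool(tie),
            }
        )
    return pd.DataFrame(rows)


def barcode_detection_rate(
    assignments: pd.DataFrame,
    all_cells: Sequence[str],
    annotations: pd.Series | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Fraction of cells with an assigned barcode, overall and per cell type.

    Confidence intervals are Jeffreys binomial intervals.  Annotation groups
    without cells give NA rows.
    """
    assigned_cells = set(
        assignments.loc[assignments["assigned"], "cell_barcode"]
    )
    detected = pd.Series(
        [c in assigned_cells for c in all_cells], index=list(all_cells)
    )

    def _row(name: str, mask: pd.Series) -> dict:
        n = int(mask.sum())
        if n == 0:
            return {"group": name, "n_cells": 0, "n_detected": 0,
                    "rate": np.nan, "ci_lower": np.nan, "ci_upper": np.nan}
        k = int(detected[mask].sum())
        alpha = 1 - ci_level
        lo = beta.ppf(alpha / 2, k + 0.5, n - k + 0.5) if k > 0 else 0.0
        hi = beta.ppf(1 - alpha / 2, k + 0.5, n - k + 0.5) if k < n else 1.0
        return {"group": name, "n_cells": n, "n_detected": k,
                "rate": k / n, "ci_lower": float(lo), "ci_upper": float(hi)}

    rows = [_row("all", pd.Series(True, index=detected.index))]
    if annotations is not None:
        annotations = annotations.reindex(detected.index)
        for name in sorted(annotations.dropna().unique()):
            rows.append(_row(str(name), annotations == name))
    return pd.DataFrame(rows)


def clone_table(
    assignments: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell clone membership joined with timepoint and cluster metadata."""
    assigned = assignments[assignments["assigned"]].copy()
    joined = assigned.merge(
        metadata, left_on="cell_barcode", right_index=True, how="left"
    )
    return joined


def clone_summary(
    clones: pd.DataFrame,
    d0_label: str = "D0",
    cluster_col: str = "cluster",
    timepoint_col: str = "timepoint",
) -> pd.DataFrame:
    """Per-clone size, cell-type breadth and before/after-conversion presence."""
    if len(clones) == 0:
        raise ValueError("clone table is empty")
    rows = []
    for cid, grp in clones.groupby("clone_id", sort=True):
        tps = grp[timepoint_col]
        rows.append(
            {
                "clone_id": cid,
                "size": len(grp),
                "n_cell_types": int(grp[cluster_col].nunique())
                if cluster_col in grp
                else np.nan,
                "present_d0": bool((tps == d0_label).any()),
                "present_post": bool((tps != d0_label).any()),
                "spans_conversion": bool(
                    (tps == d0_label).any() and (tps != d0_label).any()
                ),
            }
        )
    return pd.DataFrame(rows).sort_values("size", ascending=False).reset_index(drop=True)


def run_barcode_pipeline(
    fastq_r1: str,
    fastq_r2: str,
    whitelist_path: str,
    retained_cells: Iterable[str] | None = None,
    min_umi: int = 1,
    purity: float = 0.0,
    max_dist: int = 1,
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
) -> dict:
    """Extraction -> UMI counting -> correction -> whitelist filter -> clones."""
    records, stats = extract_barcodes(fastq_r1, fastq_r2, flank5, flank3)
    matrix = count_matrix(records)
    corrected, merge_log = correct_barcodes(matrix, max_dist=max_dist)
    whitelist = [line.strip() for line in open(whitelist_path) if line.strip()]
    filtered, filter_report = filter_whitelist(corrected, whitelist, retained_cells)
    assignments = assign_clones(filtered, min_umi=min_umi, purity=purity)
    return {
        "records": records,
        "stats": stats,
        "matrix": matrix,
        "corrected": corrected,
        "merge_log": merge_log,
        "filtered": filtered,
        "filter_report": filter_report,
        "assignments": assignments,
    }
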