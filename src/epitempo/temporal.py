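"""Cross-stage and cross-condition comparison of retained peaks.

Builds a strand-aware merged peak atlas across samples (mergeBed-style
single-linkage union of overlapping or bookended intervals), derives ON/OFF
methylation switches between adjacent stages, classifies RNAs as
continuously (CMR) or stage-specifically (SMR) methylated, and calls
differentially methylated peaks/RNAs between two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import quantify_peak

__all__ = ["merge_peaks_across_samples", "detect_switches",
           "classify_cmr_smr", "rna_presence_matrix", "detect_dmrs",
           "rna_gain_loss"]

DMR_FDR_THRESHOLD = 0.05
DMR_LOG2FC_THRESHOLD = 1.0


def merge_peaks_across_samples(peaks: pd.DataFrame,
                               sample_col: str = "sample_id",
                               samples: list[str] | None = None) -> pd.DataFrame:
    """Merge retained peaks from all samples into a union atlas.

    ``peaks`` needs columns chrom/start/end/strand plus ``sample_col``
    (and optionally name/gene_id).  Overlapping or bookended intervals on
    the same chrom and strand merge transitively; mixed-strand overlaps
    never merge.  Presence columns (one per sample) mark samples
    contributing at least one member peak, which by construction overlap
    the union interval on the same strand.
    """
    if samples is None:
        samples = sorted(peaks[sample_col].unique())
    merged_rows = []
    has_gene = "gene_id" in peaks.columns
    for (chrom, strand), grp in peaks.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values(["start", "end"]).reset_index()
        cur = None
        for row in grp.itertuples():
            if cur is not None and row.start <= cur["end"]:
                cur["end"] = max(cur["end"], row.end)
                cur["members"].append(row.index)
                cur["samples"].add(getattr(row, sample_col))
                if has_gene:
                    cur["genes"].add(row.gene_id)
            else:
                if cur is not None:
                    merged_rows.append(cur)
                cur = {"chrom": chrom, "strand": strand,
                       "start": row.start, "end": row.end,
                       "members": [row.index],
                       "samples": {getattr(row, sample_col)},
                       "genes": {row.gene_id} if has_gene else set()}
        if cur is not None:
            merged_rows.append(cur)
    out = []
    for k, m in enumerate(sorted(merged_rows,
                                 key=lambda m: (m["chrom"], m["start"], m["strand"]))):
        rec = {"merged_id": f"m{k:06d}", "chrom": m["chrom"],
               "start": int(m["start"]), "end": int(m["end"]),
               "strand": m["strand"],
               "members": ",".join(map(str, m["members"])),
               "gene_id": ",".join(sorted(m["genes"])) if m["genes"] else ""}
        for s in samples:
            rec[f"present_{s}"] = s in m["samples"]
        out.append(rec)
    cols = (["merged_id", "chrom", "start", "end", "strand", "members",
             "gene_id"] + [f"present_{s}" for s in samples])
    return pd.DataFrame(out, columns=cols).set_index("merged_id")


def detect_switches(merged: pd.DataFrame, stages: list[str],
                    presence_prefix: str = "present_") -> pd.DataFrame:
    """ON/OFF switch events between adjacent stages.

    A merged peak absent at the former stage but present at the later one
    is an ON switch; the reverse is an OFF switch.  One peak can emit
    events at several transitions.
    """
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    rows = []
    for a, b in zip(stages, stages[1:]):
        pa = merged[f"{presence_prefix}{a}"].to_numpy(bool)
        pb = merged[f"{presence_prefix}{b}"].to_numpy(bool)
        transition = f"{a}-{b}"
        for mid, gene in zip(merged.index[~pa & pb],
                             merged.loc[~pa & pb, "gene_id"]):
            rows.append({"merged_id": mid, "transition": transition,
                         "direction": "ON", "gene_id": gene})
        for mid, gene in zip(merged.index[pa & ~pb],
                             merged.loc[pa & ~pb, "gene_id"]):
            rows.append({"merged_id": mid, "transition": transition,
                         "direction": "OFF", "gene_id": gene})
    return pd.DataFrame(rows, columns=["merged_id", "transition",
                                       "direction", "gene_id"])


def rna_presence_matrix(retained: pd.DataFrame, stages: list[str],
                        sample_suffix: str = "_WT") -> pd.DataFrame:
    """Per-RNA, per-stage methylation booleans (>= 1 retained peak)."""
    rows = {}
    for stage in stages:
        sid = f"{stage}{sample_suffix}"
        genes = set(retained.loc[retained["sample_id"] == sid, "gene_id"])
        rows[stage] = genes
    all_genes = sorted(set().union(*rows.values())) if rows else []
    return pd.DataFrame({stage: [g in rows[stage] for g in all_genes]
                         for stage in stages}, index=all_genes)


def classify_cmr_smr(presence: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Exclusive methylation-class labels from a gene x stage matrix.

    CMR: methylated at every stage; SMR:<stage>: methylated at exactly
    that stage; other: any other non-empty schedule; unmethylated: none.
    """
    stages = list(presence.columns)
    mat = presence.to_numpy(bool)
    n_on = mat.sum(axis=1)
    labels = np.full(len(presence), "other", dtype=object)
    labels[n_on == 0] = "unmethylated"
    labels[n_on == len(stages)] = "CMR"
    for j, stage in enumerate(stages):
        only = (n_on == 1) & mat[:, j]
        labels[only] = f"SMR:{stage}"
    out = presence.copy()
    out["class_label"] = labels
    tally = {"CMR": int((labels == "CMR").sum())}
    for stage in stages:
        tally[f"SMR:{stage}"] = int((labels == f"SMR:{stage}").sum())
    tally["other"] = int((labels == "other").sum())
    tally["unmethylated"] = int((labels == "unmethylated").sum())
    tally["methylated_total"] = int((n_on > 0).sum())
    return out, tally


@dataclass(frozen=True)
class _LibPair:
    ip_total: float
    input_total: float


def detect_dmrs(counts_x: pd.DataFrame, counts_y: pd.DataFrame,
                lib_x: tuple[float, float], lib_y: tuple[float, float],
                fdr_threshold: float = DMR_FDR_THRESHOLD,
                log2fc_threshold: float = DMR_LOG2FC_THRESHOLD) -> pd.DataFrame:
    """Differential methylation of condition x (e.g. KO) vs y (e.g. WT).

    ``counts_x``/``counts_y`` index peaks over a common atlas with columns
    A, D, C and a boolean ``retained`` (passes the per-condition peak
    criteria).  log2FC compares the two enrichment scores; the p-value is
    Fisher's exact test on the IP/input split, with input counts rescaled
    by the per-condition library ratio B/E so both margins sit on the IP
    scale; BH controls the FDR across tested peaks.

    Categories: ``gain``/``loss`` when the peak is retained in exactly one
    condition; ``hyper``/``hypo`` when retained in both with FDR < 0.05
    and |log2FC| > 1; ``unchanged`` otherwise.
    """
    common = counts_x.index.intersection(counts_y.index)
    Bx, Ex = lib_x
    By, Ey = lib_y
    rows = []
    for pid in common:
        rx, ry = counts_x.loc[pid], counts_y.loc[pid]
        qx = quantify_peak(rx["A"], rx["D"], rx["C"], Bx, Ex)
        qy = quantify_peak(ry["A"], ry["D"], ry["C"], By, Ey)
        ret_x = bool(rx.get("retained", True))
        ret_y = bool(ry.get("retained", True))
        rec = {"peak_id": pid,
               "gene_id": rx.get("gene_id", ry.get("gene_id", "")),
               "score_x": qx.enrichment, "score_y": qy.enrichment,
               "p": np.nan, "log2fc": np.nan}
        if ret_x and not ret_y:
            rec["category"] = "gain"
        elif ret_y and not ret_x:
            rec["category"] = "loss"
        elif not ret_x and not ret_y:
            rec["category"] = "unchanged"
        else:
            if qy.enrichment == 0 or not qy.enrichment_defined \
                    or not qx.enrichment_defined or qx.enrichment == 0:
                rec["category"] = "unchanged"
            else:
                rec["log2fc"] = float(np.log2(qx.enrichment / qy.enrichment))
                dx = int(round(rx["D"] * Bx / Ex))
                dy = int(round(ry["D"] * By / Ey))
                table = [[int(rx["A"]), dx], [int(ry["A"]), dy]]
                rec["p"] = float(stats.fisher_exact(table)[1])
                rec["category"] = None  # assigned after BH below
        rows.append(rec)
    df = pd.DataFrame(rows).set_index("peak_id") if rows else pd.DataFrame(
        columns=["gene_id", "score_x", "score_y", "p", "log2fc",
                 "category", "fdr"])
    if len(df):
        df["fdr"] = np.nan
        tested = df["p"].notna()
        if tested.any():
            df.loc[tested, "fdr"] = multipletests(
                df.loc[tested, "p"], method="fdr_bh")[1]
        pend = df["category"].isna()
        sig = pend & (df["fdr"] < fdr_threshold) & \
            (df["log2fc"].abs() > log2fc_threshold)
        df.loc[sig & (df["log2fc"] > 0), "category"] = "hyper"
        df.loc[sig & (df["log2fc"] < 0), "category"] = "hypo"
        df.loc[df["category"].isna(), "category"] = "unchanged"
    return df


def rna_gain_loss(retained_x: set, retained_y: set) -> pd.DataFrame:
    """RNA-level gain/loss: methylated in exactly one condition.

    ``retained_x``/``retained_y`` are the sets of RNA ids carrying at
    least one retained peak in each condition (x = perturbed).
    """
    rows = ([{"gene_id": g, "category": "gain"}
             for g in sorted(retained_x - retained_y)]
            + [{"gene_id": g, "category": "loss"}
               for g in sorted(retained_y - retained_x)])
    return pd.DataFrame(rows, columns=["gene_id", "category"])
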