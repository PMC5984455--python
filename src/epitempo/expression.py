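"""Transcript expression (FPKM), the expressed-transcript filter, and the
methylation-expression correlation screen.

FPKM for a transcript is count * 1e9 / (library_size * length); a
transcript is called expressed when FPKM > 0.2 (strict).  The correlation
screen pairs each RNA's per-stage methylation level (enrichment scores)
with its per-stage FPKM, computes Pearson's r over the four stages, and
classifies high-confidence pairs at |r| > 0.95 with two-sided P < 0.05
(t distribution with n - 2 = 2 degrees of freedom).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["compute_fpkm", "fpkm_table", "correlate_methylation_expression",
           "EXPRESSED_FPKM_THRESHOLD", "CORRELATION_R_THRESHOLD",
           "CORRELATION_P_THRESHOLD"]

EXPRESSED_FPKM_THRESHOLD = 0.2
CORRELATION_R_THRESHOLD = 0.95
CORRELATION_P_THRESHOLD = 0.05


def compute_fpkm(count: float, length: float, lib_size: float) -> float:
    """FPKM = count * 1e9 / (lib_size * length)."""
    if length <= 0:
        raise ValueError(f"transcript length must be positive, got {length}")
    if lib_size <= 0:
        raise ValueError(f"library size must be positive, got {lib_size}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count * 1e9 / (lib_size * length)


def is_expressed(fpkm: float) -> bool:
    return fpkm > EXPRESSED_FPKM_THRESHOLD


def fpkm_table(transcript_counts: pd.DataFrame, libstats: pd.DataFrame,
               stages: list[str], sample_suffix: str = "_WT") -> pd.DataFrame:
    """Gene x stage FPKM matrix from per-sample input-library counts.

    ``transcript_counts`` has rows gene_id/sample_id/input_count/length;
    ``libstats`` is indexed by sample_id with an ``input_total`` column.
    """
    frames = {}
    for stage in stages:
        sid = f"{stage}{sample_suffix}"
        sub = transcript_counts[transcript_counts["sample_id"] == sid]
        lib = float(libstats.loc[sid, "input_total"])
        fpkm = sub["input_count"].to_numpy(float) * 1e9 / (
            lib * sub["length"].to_numpy(float))
        frames[stage] = pd.Series(fpkm, index=sub["gene_id"].to_numpy())
    return pd.DataFrame(frames)


def correlate_methylation_expression(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    r_threshold: float = CORRELATION_R_THRESHOLD,
    p_threshold: float = CORRELATION_P_THRESHOLD,
    require_expressed: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Pearson screen of per-RNA methylation vs expression trajectories.

    ``meth`` and ``expr`` are RNA x stage matrices over the same stage
    order; RNAs present in both (and, if ``require_expressed``, expressed
    at >= 1 stage) are tested.  RNAs with zero variance in either vector
    are skipped with a reason.  Sign classes: positive (r > 0.95, P <
    0.05), negative (r < -0.95, P < 0.05), none otherwise.

    Returns the per-RNA table and a tally of positive/negative/none/
    skipped.
    """
    common = meth.index.intersection(expr.index)
    rows = []
    tally = {"positive": 0, "negative": 0, "none": 0, "skipped": 0,
             "not_expressed": 0}
    for rna in common:
        m = meth.loc[rna].to_numpy(float)
        e = expr.loc[rna].to_numpy(float)
        if require_expressed and not np.any(e > EXPRESSED_FPKM_THRESHOLD):
            tally["not_expressed"] += 1
            continue
        if np.std(m) == 0 or np.std(e) == 0:
            rows.append({"rna_id": rna, "r": np.nan, "p": np.nan,
                         "sign_class": "skipped", "reason": "zero_variance"})
            tally["skipped"] += 1
            continue
        r, p = stats.pearsonr(m, e)
        if r > r_threshold and p < p_threshold:
            cls = "positive"
        elif r < -r_threshold and p < p_threshold:
            cls = "negative"
        else:
            cls = "none"
        tally[cls] += 1
        rows.append({"rna_id": rna, "r": float(r), "p": float(p),
                     "sign_class": cls, "reason": ""})
    df = pd.DataFrame(rows, columns=["rna_id", "r", "p", "sign_class",
                                     "reason"])
    return (df.set_index("rna_id") if len(df) else df), tally


def methylation_level_matrix(retained: pd.DataFrame, stages: list[str],
                             sample_suffix: str = "_WT",
                             aggregate: str = "max") -> pd.DataFrame:
    """Per-RNA, per-stage methylation level from retained peak scores.

    The level is the maximum (default) or mean retained-peak enrichment
    score of the RNA at that stage; stages without a retained peak
    contribute 0 so every RNA has a complete trajectory.  Infinite scores
    (input dropout) are excluded from aggregation.
    """
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    finite = retained[np.isfinite(retained["enrichment"])]
    cols = {}
    for stage in stages:
        sid = f"{stage}{sample_suffix}"
        sub = finite[finite["sample_id"] == sid]
        agg = sub.groupby("gene_id")["enrichment"].agg(aggregate)
        cols[stage] = agg
    mat = pd.DataFrame(cols).fillna(0.0)
    return mat
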