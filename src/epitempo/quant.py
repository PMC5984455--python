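"""Peak-level read counting and IP/input enrichment statistics.

The quantification contract mirrors the conventional MeRIP-seq peak score:
for peak *i* in library *j*,

    ip_fpkm    a = A * 1e9 / (B * C)
    input_fpkm b = D * 1e9 / (E * C)
    enrichment c = a / b

where A (D) is the read count on the peak in the IP (input) library,
B (E) the total mapped reads of the IP (input) library, and C the peak
length in nucleotides.  Counting follows ``coverageBed -s -split -counts
-F 0.50`` semantics: a read is counted iff at least half of its aligned
length overlaps the peak on the same strand, split reads contributing
their block-wise overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PeakQuant",
    "AlignedRead",
    "ReadIndex",
    "quantify_peak",
    "count_reads_in_interval",
    "filter_peaks",
    "call_candidate_peaks",
    "compare_enrichment_distributions",
    "FDR_THRESHOLD",
    "IP_FPKM_THRESHOLD",
    "ENRICHMENT_THRESHOLD",
]

# Peak retention thresholds (strict inequalities).
FDR_THRESHOLD = 0.05
IP_FPKM_THRESHOLD = 1.0
ENRICHMENT_THRESHOLD = 1.5


@dataclass(frozen=True)
class PeakQuant:
    """Peak count statistics and the derived FPKM/enrichment values."""

    A: float
    D: float
    C: float
    B: float
    E: float
    ip_fpkm: float
    input_fpkm: float
    enrichment: float
    #: False when D == 0, in which case ``enrichment`` is a sentinel
    #: (inf for A > 0, 0 for A == 0) and must not enter distribution plots.
    enrichment_defined: bool = True


def quantify_peak(A: float, D: float, C: float, B: float, E: float) -> PeakQuant:
    """Compute ip_fpkm, input_fpkm and the enrichment score for one peak.

    Parameters are the raw ingredients: peak counts ``A`` (IP) and ``D``
    (input), peak length ``C`` and library totals ``B`` (IP), ``E`` (input).

    Raises
    ------
    ValueError
        If ``C``, ``B`` or ``E`` is not positive, or a count is negative.
    """
    if C <= 0:
        raise ValueError(f"peak length must be positive, got C={C}")
    if B <= 0 or E <= 0:
        raise ValueError(f"library totals must be positive, got B={B}, E={E}")
    if A < 0 or D < 0:
        raise ValueError(f"read counts must be non-negative, got A={A}, D={D}")
    a = A * 1e9 / (B * C)
    b = D * 1e9 / (E * C)
    if D == 0:
        c = float("inf") if A > 0 else 0.0
        return PeakQuant(A, D, C, B, E, a, b, c, enrichment_defined=False)
    return PeakQuant(A, D, C, B, E, a, b, a / b, enrichment_defined=True)


@dataclass(frozen=True)
class AlignedRead:
    """A strand-aware aligned read as one or more genomic blocks.

    A contiguous (BED6-style) read has a single block; a spliced
    (BED12-style) read carries one block per aligned segment.  The overlap
    fraction used for counting is relative to the summed block length.
    """

    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)


class ReadIndex:
    """Interval index over aligned reads, per (chrom, strand)."""

    def __init__(self, reads: Iterable[AlignedRead]):
        self.reads: list[AlignedRead] = list(reads)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for idx, read in enumerate(self.reads):
            key = (read.chrom, read.strand)
            tree = self._trees.setdefault(key, IntervalTree())
            for s, e in read.blocks:
                if e > s:
                    tree.addi(s, e, idx)

    def overlapping(self, chrom: str, start: int, end: int,
                    strand: str | None) -> dict[int, int]:
        """Map read index -> total overlapped bases with [start, end)."""
        overlaps: dict[int, int] = {}
        strands = [strand] if strand is not None else ["+", "-", "."]
        for st in strands:
            tree = self._trees.get((chrom, st))
            if tree is None:
                continue
            for iv in tree.overlap(start, end):
                ov = min(iv.end, end) - max(iv.begin, start)
                if ov > 0:
                    overlaps[iv.data] = overlaps.get(iv.data, 0) + ov
        return overlaps


def count_reads_in_interval(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    reads: ReadIndex,
    min_overlap_frac: float = 0.50,
    same_strand: bool = True,
) -> int:
    """Count reads overlapping a peak with >= ``min_overlap_frac`` of their
    aligned length, strand-matched by default (coverageBed ``-s -F``).

    Raises
    ------
    ValueError
        If ``same_strand`` is requested and a candidate read is strandless.
    """
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    overlaps = reads.overlapping(chrom, start, end, None)
    n = 0
    for idx, ov in overlaps.items():
        read = reads.reads[idx]
        if same_strand:
            if read.strand not in ("+", "-"):
                raise ValueError(
                    f"strandless read at index {idx} with same_strand=True")
            if read.strand != strand:
                continue
        if ov >= min_overlap_frac * read.length:
            n += 1
    return n


def filter_peaks(
    peaks: pd.DataFrame,
    fdr_threshold: float = FDR_THRESHOLD,
    ip_fpkm_threshold: float = IP_FPKM_THRESHOLD,
    enrichment_threshold: float = ENRICHMENT_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three peak-retention criteria (all strict inequalities):
    FDR < 0.05, ip_fpkm > 1 and enrichment > 1.5.

    ``peaks`` must carry columns ``fdr``, ``ip_fpkm`` and ``enrichment``.
    Peaks with missing FDR are rejected.  Returns the retained subset and a
    per-criterion rejection tally.
    """
    fdr = peaks["fdr"]
    fail_fdr = ~(fdr < fdr_threshold)  # NaN fails too
    fail_ip = ~(peaks["ip_fpkm"] > ip_fpkm_threshold)
    fail_es = ~(peaks["enrichment"] > enrichment_threshold)
    keep = ~(fail_fdr | fail_ip | fail_es)
    tally = {
        "input": int(len(peaks)),
        "retained": int(keep.sum()),
        "rejected_fdr": int(fail_fdr.sum()),
        "rejected_ip_fpkm": int(fail_ip.sum()),
        "rejected_enrichment": int(fail_es.sum()),
        "rejected_missing_fdr": int(fdr.isna().sum()),
    }
    return peaks.loc[keep].copy(), tally


def region_enrichment_pvalues(A: np.ndarray, D: np.ndarray,
                              B: float, E: float) -> np.ndarray:
    """One-sided binomial test of IP excess per region.

    Conditional on n = A + D, A ~ Binomial(n, p0) under no enrichment with
    p0 = B / (B + E); the p-value is P(X >= A).
    """
    A = np.asarray(A, dtype=np.int64)
    D = np.asarray(D, dtype=np.int64)
    if np.any(A < 0) or np.any(D < 0):
        raise ValueError("negative counts")
    p0 = B / (B + E)
    n = A + D
    # P(X >= A) = sf(A-1); n == 0 gives p = 1
    p = np.ones(len(A))
    nz = n > 0
    p[nz] = stats.binom.sf(A[nz] - 1, n[nz], p0)
    return p


def call_candidate_peaks(
    ip_reads: ReadIndex,
    input_reads: ReadIndex,
    transcripts: Sequence,
    ip_total: float,
    input_total: float,
    window: int = 100,
    step: int = 50,
    fdr_threshold: float = FDR_THRESHOLD,
    min_overlap_frac: float = 0.50,
) -> pd.DataFrame:
    """Simple sliding-window candidate peak caller (analysis plumbing).

    Windows of ``window`` nt advance by ``step`` along each reference
    transcript's exons in genomic space.  Per window, IP vs input counts are
    tested one-sided (binomial conditional on the window total, null
    proportion B/(B+E)); BH adjustment runs across all windows of all
    transcripts; adjacent/overlapping significant windows merge into peaks
    whose FDR is the minimum member window FDR.

    Returns a BED-like DataFrame: chrom, start, end, name, score, strand,
    fdr, gene_id, transcript_id.
    """
    if ip_total <= 0 or input_total <= 0:
        raise ValueError("empty library")
    rows = []  # (tx, gstart, gend, A, D)
    for tx in transcripts:
        for es, ee in tx.exons:
            pos = es
            while pos < ee:
                wend = min(pos + window, ee)
                if wend - pos >= max(20, window // 5):
                    A = count_reads_in_interval(tx.chrom, pos, wend, tx.strand,
                                                ip_reads, min_overlap_frac)
                    D = count_reads_in_interval(tx.chrom, pos, wend, tx.strand,
                                                input_reads, min_overlap_frac)
                    rows.append((tx, pos, wend, A, D))
                pos += step
    if not rows:
        return _empty_peak_frame()
    A = np.array([r[3] for r in rows])
    D = np.array([r[4] for r in rows])
    pvals = region_enrichment_pvalues(A, D, ip_total, input_total)
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    sig = fdrs < fdr_threshold
    # merge adjacent significant windows per transcript
    peaks = []
    by_tx: dict[int, list[int]] = {}
    for i, r in enumerate(rows):
        if sig[i]:
            by_tx.setdefault(id(r[0]), []).append(i)
    for idxs in by_tx.values():
        idxs.sort(key=lambda i: rows[i][1])
        cur = None
        for i in idxs:
            tx, s, e, _, _ = rows[i]
            if cur is not None and s <= cur[2]:
                cur[2] = max(cur[2], e)
                cur[3] = min(cur[3], fdrs[i])
            else:
                if cur is not None:
                    peaks.append(cur)
                cur = [tx, s, e, fdrs[i]]
        if cur is not None:
            peaks.append(cur)
    out = []
    for k, (tx, s, e, fdr) in enumerate(sorted(peaks, key=lambda p: (p[0].chrom, p[1]))):
        out.append({
            "chrom": tx.chrom, "start": int(s), "end": int(e),
            "name": f"peak_{k}", "score": 0, "strand": tx.strand,
            "fdr": float(fdr), "gene_id": tx.gene_id,
            "transcript_id": tx.transcript_id,
        })
    return pd.DataFrame(out) if out else _empty_peak_frame()


def _empty_peak_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "name", "score",
                                 "strand", "fdr", "gene_id", "transcript_id"])


def compare_enrichment_distributions(scores_x, scores_y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison of two
    enrichment-score (or log2 FPKM) distributions; ties mid-ranked.
    """
    x = np.asarray(scores_x, dtype=float)
    y = np.asarray(scores_y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
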