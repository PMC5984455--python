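"""Single-end read preprocessing: adapter removal, 3' quality trimming and
quality-based retention.

The three criteria, applied in order to every read:

1. truncate at the leftmost occurrence of the adapter ``AGATCGGAAG``
   allowing at most two mismatched bases;
2. trim bases with quality < 20 off the 3' end;
3. retain only reads longer than 70 nt in which more than 70% of bases
   have quality > 25.

All inequalities are strict.  ``N`` bases count as mismatches in the
adapter scan and as low-quality (<= 25) bases in the retention test.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Read", "PreprocessResult", "find_adapter", "preprocess_read",
           "process_fastq", "DEFAULT_ADAPTER"]

DEFAULT_ADAPTER = "AGATCGGAAG"


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})")


@dataclass(frozen=True)
class PreprocessResult:
    read: Optional[Read]       # processed read; None when discarded
    kept: bool
    adapter_offset: Optional[int]   # truncation point, None if no adapter found
    quality_trimmed: int            # bases removed by 3' quality trim
    reason: Optional[str]           # discard reason code, None when kept


def _hamming(a: str, b: str) -> int:
    # N never matches
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def find_adapter(sequence: str,
                 adapter: str = DEFAULT_ADAPTER,
                 max_mismatch: int = 2,
                 allow_partial_suffix: bool = False) -> Optional[int]:
    """Leftmost offset at which the adapter starts, or None.

    Full-length matches require Hamming distance <= ``max_mismatch``.  With
    ``allow_partial_suffix``, a read suffix of length k in [5, len(adapter))
    matching the adapter prefix with at most floor(max_mismatch * k /
    len(adapter)) mismatches also counts, so partially sequenced adapters at
    the 3' end are trimmed too.  The leftmost hit of either kind wins.
    """
    n, m = len(sequence), len(adapter)
    for i in range(n):
        k = min(m, n - i)
        if k == m:
            if _hamming(sequence[i:i + m], adapter) <= max_mismatch:
                return i
        elif allow_partial_suffix and k >= 5:
            if _hamming(sequence[i:], adapter[:k]) <= (max_mismatch * k) // m:
                return i
        else:
            break
    return None


def preprocess_read(read: Read,
                    adapter: str = DEFAULT_ADAPTER,
                    max_mismatch: int = 2,
                    trim_q: int = 20,
                    min_len: int = 70,
                    frac: float = 0.70,
                    frac_q: int = 25,
                    allow_partial_suffix: bool = False) -> PreprocessResult:
    """Apply the three filtering criteria to one read.

    Returns the processed read plus a per-step audit record; discarded
    reads carry a reason code (``empty``, ``too_short`` or
    ``low_quality_fraction``).
    """
    seq, qual = read.sequence, list(read.qualities)

    offset = find_adapter(seq, adapter, max_mismatch, allow_partial_suffix)
    if offset is not None:
        seq, qual = seq[:offset], qual[:offset]

    trimmed = 0
    while qual and qual[-1] < trim_q:
        qual.pop()
        trimmed += 1
    seq = seq[:len(qual)]

    if not seq:
        return PreprocessResult(None, False, offset, trimmed, "empty")
    if len(seq) <= min_len:
        return PreprocessResult(None, False, offset, trimmed, "too_short")
    n_good = sum(1 for base, q in zip(seq, qual) if q > frac_q and base != "N")
    if n_good / len(seq) <= frac:
        return PreprocessResult(None, False, offset, trimmed,
                                "low_quality_fraction")
    out = Read(read.id, seq, tuple(qual))
    return PreprocessResult(out, True, offset, trimmed, None)


def _records_to_reads(records: Iterable[SeqRecord]) -> Iterator[Read]:
    for rec in records:
        yield Read(rec.id, str(rec.seq).upper(),
                   tuple(rec.letter_annotations["phred_quality"]))


def process_fastq(fastq_in: str, fastq_out: str,
                  report_path: Optional[str] = None,
                  **kwargs) -> dict:
    """Stream a FASTQ file through ``preprocess_read``.

    Writes retained reads (Phred+33) to ``fastq_out`` and, optionally, a
    TSV summary to ``report_path``.  Returns the summary statistics.
    """
    n_in = n_out = n_adapter = 0
    total_out_len = 0
    reasons: dict[str, int] = {}
    with open(fastq_out, "w") as fh:
        for read in _records_to_reads(SeqIO.parse(fastq_in, "fastq")):
            n_in += 1
            res = preprocess_read(read, **kwargs)
            if res.adapter_offset is not None:
                n_adapter += 1
            if res.kept:
                n_out += 1
                total_out_len += len(res.read.sequence)
                rec = SeqRecord(Seq(res.read.sequence), id=res.read.id,
                                description="")
                rec.letter_annotations["phred_quality"] = list(res.read.qualities)
                SeqIO.write(rec, fh, "fastq")
            else:
                reasons[res.reason] = reasons.get(res.reason, 0) + 1
    statistics = {
        "reads_in": n_in,
        "reads_out": n_out,
        "adapters_trimmed": n_adapter,
        "mean_retained_length": (total_out_len / n_out) if n_out else 0.0,
        **{f"discarded_{k}": v for k, v in sorted(reasons.items())},
    }
    if report_path:
        with open(report_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["metric", "value"])
            for k, v in statistics.items():
                writer.writerow([k, v])
    return statistics
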