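"""Reference transcriptome handling and the five-region transcript partition.

The reference transcriptome keeps the longest transcript of each gene.
For coding transcripts a five-region partition is carved in transcript
coordinates: 5'UTR, a 300-nt window centred on the start codon, CDS, a
300-nt window centred on the stop codon, and 3'UTR.  The codon windows are
anchored at the first nucleotide of their codon (window = anchor-150 ..
anchor+150), clipped at transcript ends; when a short CDS makes the two
windows meet, they split at the midpoint between the anchors with the
start window taking the left half.

Coordinates are 0-based half-open internally; GTF input (1-based
inclusive) is converted on parse.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gffutils

__all__ = ["TranscriptModel", "RegionPartition", "parse_gtf",
           "select_reference_transcript", "partition_regions",
           "label_position", "REGION_LABELS", "CODON_WINDOW"]

#: total width of a codon-centred region, nt
CODON_WINDOW = 300
HALF_WINDOW = CODON_WINDOW // 2

REGION_LABELS = ("utr5", "start_codon", "cds", "stop_codon", "utr3")


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are genomic intervals (0-based half-open), sorted by genomic
    start; transcript coordinates run 5'->3' in transcript orientation, so
    on the minus strand transcript offset 0 is the highest genomic
    coordinate.  ``cds_start``/``cds_end`` are transcript-coordinate
    offsets of the first nucleotide of the start codon and of the first
    nucleotide after the stop codon (the annotated CDS here includes the
    stop codon); ``None`` for non-coding transcripts.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    _cumlens: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self):
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        self.exons = exons
        cum, total = [], 0
        for s, e in exons:
            cum.append(total)
            total += e - s
        self._cumlens = tuple(cum)
        self._total = total
        if self.is_coding:
            if not (0 <= self.cds_start < self.cds_end <= total):
                raise ValueError(f"{self.transcript_id}: CDS outside transcript")

    # -- lengths ---------------------------------------------------------
    @property
    def total_length(self) -> int:
        return self._total

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    @property
    def utr5_len(self) -> int:
        return self.cds_start if self.is_coding else 0

    @property
    def cds_len(self) -> int:
        return (self.cds_end - self.cds_start) if self.is_coding else 0

    @property
    def utr3_len(self) -> int:
        return (self.total_length - self.cds_end) if self.is_coding else 0

    # -- coordinate mapping ---------------------------------------------
    def genomic_to_transcript(self, gpos: int) -> Optional[int]:
        """Transcript offset of genomic position ``gpos`` (exonic only)."""
        for (s, e), cum in zip(self.exons, self._cumlens):
            if s <= gpos < e:
                plus_offset = cum + (gpos - s)
                if self.strand == "+":
                    return plus_offset
                return self.total_length - 1 - plus_offset
        return None

    def transcript_to_genomic(self, offset: int) -> int:
        """Genomic position of transcript offset ``offset``."""
        if not 0 <= offset < self.total_length:
            raise ValueError(f"offset {offset} outside [0, {self.total_length})")
        plus_offset = offset if self.strand == "+" else self.total_length - 1 - offset
        for (s, e), cum in zip(self.exons, self._cumlens):
            if cum <= plus_offset < cum + (e - s):
                return s + (plus_offset - cum)
        raise AssertionError("unreachable")

    def transcript_interval_to_genomic_blocks(
            self, t0: int, t1: int) -> list[tuple[int, int]]:
        """Genomic blocks covered by transcript interval [t0, t1)."""
        if not 0 <= t0 < t1 <= self.total_length:
            raise ValueError(f"bad transcript interval [{t0}, {t1})")
        if self.strand == "+":
            p0, p1 = t0, t1
        else:
            p0, p1 = self.total_length - t1, self.total_length - t0
        blocks = []
        for (s, e), cum in zip(self.exons, self._cumlens):
            lo = max(p0, cum)
            hi = min(p1, cum + (e - s))
            if hi > lo:
                blocks.append((s + lo - cum, s + hi - cum))
        return blocks

    def exonic_overlap(self, gstart: int, gend: int) -> list[tuple[int, int]]:
        """Genomic sub-intervals of [gstart, gend) covered by exons."""
        out = []
        for s, e in self.exons:
            lo, hi = max(s, gstart), min(e, gend)
            if hi > lo:
                out.append((lo, hi))
        return out


@dataclass(frozen=True)
class RegionPartition:
    """The carved five-region partition of one coding transcript.

    Each region is a half-open transcript-coordinate interval (possibly
    empty); together they are disjoint and cover [0, total_length).
    """

    utr5: tuple[int, int]
    start_codon: tuple[int, int]
    cds: tuple[int, int]
    stop_codon: tuple[int, int]
    utr3: tuple[int, int]

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {label: getattr(self, label) for label in REGION_LABELS}


def partition_regions(t: TranscriptModel) -> RegionPartition:
    """Carve the five-region partition of a coding transcript.

    Raises
    ------
    ValueError
        For non-coding transcripts (excluded from metagene analyses).
    """
    if not t.is_coding:
        raise ValueError(f"{t.transcript_id}: non-coding transcript has no partition")
    L = t.total_length
    a1 = t.cds_start                # first nucleotide of the start codon
    a2 = t.cds_end - 3              # first nucleotide of the stop codon
    ws_lo, ws_hi = max(0, a1 - HALF_WINDOW), min(L, a1 + HALF_WINDOW)
    wt_lo, wt_hi = max(0, a2 - HALF_WINDOW), min(L, a2 + HALF_WINDOW)
    if wt_lo < ws_hi:
        # short CDS: split at the midpoint between anchors, start wins left
        boundary = (a1 + a2) // 2 + 1
        ws_hi = min(ws_hi, boundary)
        wt_lo = max(wt_lo, boundary, ws_hi)
    return RegionPartition(
        utr5=(0, ws_lo),
        start_codon=(ws_lo, ws_hi),
        cds=(ws_hi, wt_lo),
        stop_codon=(wt_lo, wt_hi),
        utr3=(wt_hi, L),
    )


def label_position(partition: RegionPartition, offset: int) -> str:
    """Five-region label of a transcript-coordinate position."""
    for label, (lo, hi) in partition.as_dict().items():
        if lo <= offset < hi:
            return label
    raise ValueError(f"offset {offset} not covered by partition {partition}")


def select_reference_transcript(
    transcripts: Sequence[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """Pick the longest transcript (summed exon length) per gene.

    Ties break to the lexicographically smaller transcript_id so the
    choice is deterministic.
    """
    best: dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = best.get(t.gene_id)
        if (cur is None
                or t.total_length > cur.total_length
                or (t.total_length == cur.total_length
                    and t.transcript_id < cur.transcript_id)):
            best[t.gene_id] = t
    return best


def parse_gtf(path: str) -> list[TranscriptModel]:
    """Parse a GTF annotation into TranscriptModels.

    Tolerant of attribute dialects (quoted or bare gene_id/transcript_id).
    Exon features define transcript structure; CDS features, when present,
    define the coding span (assumed stop-codon inclusive).  GTF 1-based
    inclusive coordinates are converted to 0-based half-open.
    """
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes["gene_id"][0]
        entry = by_tx.setdefault(tx_id, {
            "gene_id": gene_id, "chrom": feat.seqid, "strand": feat.strand,
            "exons": [], "cds": []})
        # gffutils keeps GFF 1-based starts; convert to 0-based half-open
        interval = (feat.start - 1, feat.end)
        entry["exons" if feat.featuretype == "exon" else "cds"].append(interval)
    models = []
    for tx_id, entry in by_tx.items():
        if not entry["exons"]:
            raise ValueError(f"{tx_id}: no exon features")
        model = TranscriptModel(
            gene_id=entry["gene_id"], transcript_id=tx_id,
            chrom=entry["chrom"], strand=entry["strand"],
            exons=tuple(sorted(entry["exons"])))
        if entry["cds"]:
            lo = min(s for s, _ in entry["cds"])
            hi = max(e for _, e in entry["cds"])
            t_lo = model.genomic_to_transcript(lo)
            t_hi = model.genomic_to_transcript(hi - 1)
            if t_lo is None or t_hi is None:
                raise ValueError(f"{tx_id}: CDS outside exons")
            cds_start, cds_last = sorted((t_lo, t_hi))
            model = TranscriptModel(
                gene_id=entry["gene_id"], transcript_id=tx_id,
                chrom=entry["chrom"], strand=entry["strand"],
                exons=model.exons, cds_start=cds_start, cds_end=cds_last + 1)
        models.append(model)
    models.sort(key=lambda m: (m.gene_id, m.transcript_id))
    return models


def write_bed12(models: Sequence[TranscriptModel], path: str) -> None:
    """Write reference transcripts as BED12 for inspection."""
    with open(path, "w") as fh:
        for t in sorted(models, key=lambda m: (m.chrom, m.exons[0][0])):
            chrom_start = t.exons[0][0]
            chrom_end = t.exons[-1][1]
            if t.is_coding:
                g1 = t.transcript_to_genomic(t.cds_start)
                g2 = t.transcript_to_genomic(t.cds_end - 1)
                thick_start, thick_end = min(g1, g2), max(g1, g2) + 1
            else:
                thick_start = thick_end = chrom_start
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - chrom_start) for s, _ in t.exons)
            fh.write("\t".join(map(str, [
                t.chrom, chrom_start, chrom_end, t.transcript_id, 0, t.strand,
                thick_start, thick_end, "0,0,0", len(t.exons), sizes, starts,
            ])) + "\n")
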