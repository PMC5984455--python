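"""Synthetic MeRIP-seq generator with planted ground truth.

The generator emulates the data structures the temporal analysis assumes:
four developmental stages (P7, P14, P21, P60) in two conditions (WT and a
demethylase-knockout compared at the first stage), paired IP/input
libraries, per-peak IP enrichment factors, stage-resolved methylation
schedules (continuous, stage-specific, switching) and expression
trajectories optionally coupled to methylation.

Three generators are exposed:

* :func:`generate_truth` — transcript annotation plus the planted truth
  (classes, presence schedule, enrichment factors, expression);
* :func:`simulate_counts` — per-peak IP/input counts and library totals
  under a Poisson (optionally negative-binomial) count law.  Library
  totals are declared metadata (the simulated regions are a subsample of
  each library), so the enrichment score a/b recovers the planted factor
  in expectation;
* :func:`simulate_fastq` — raw reads with adapters planted at recorded
  offsets, the fixture for the preprocessing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .transcripts import (TranscriptModel, partition_regions, label_position,
                          select_reference_transcript)

__all__ = ["SimConfig", "SimTruth", "SimCounts", "generate_truth",
           "simulate_counts", "simulate_reads", "simulate_fastq",
           "write_gtf", "DEFAULT_STAGES", "SWITCH_PATTERNS"]

DEFAULT_STAGES = ("P7", "P14", "P21", "P60")

#: presence schedules with exactly one ON or OFF transition that are
#: neither continuous nor single-stage
SWITCH_PATTERNS = ((0, 1, 1, 1), (0, 0, 1, 1), (1, 1, 1, 0), (1, 1, 0, 0))

#: planted placement odds of a peak over the five transcript regions;
#: start/stop-codon-heavy, as observed in neural tissue profiles
REGION_WEIGHTS = {"utr5": 0.05, "start_codon": 0.25, "cds": 0.30,
                  "stop_codon": 0.30, "utr3": 0.10}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment."""

    n_genes: int = 1000
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    conditions: tuple[str, ...] = ("WT", "KO")
    #: declared total mapped reads per library
    mean_depth: float = 2.0e7
    #: fold IP enrichment at methylated sites
    enrichment_factor_range: tuple[float, float] = (3.0, 10.0)
    #: gene fractions per methylation class; remainder is unmethylated
    cmr_fraction: float = 0.40
    smr_fraction_each: float = 0.05
    switching_fraction: float = 0.20
    #: fraction of CMR genes whose expression tracks (+) or opposes (-)
    #: their methylation trajectory
    corr_fraction: float = 0.30
    #: knockout perturbation fractions at the first stage
    dmr_hyper_fraction: float = 0.05
    dmr_hypo_fraction: float = 0.05
    dmr_loss_fraction: float = 0.05
    dmr_gain_fraction: float = 0.10
    peak_length_range: tuple[int, int] = (100, 300)
    read_length: int = 100
    multi_transcript_fraction: float = 0.10
    noncoding_fraction: float = 0.05
    count_model: str = "poisson"        # "poisson" | "nb"
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self):
        total = (self.cmr_fraction + 4 * self.smr_fraction_each
                 + self.switching_fraction)
        if total > 1 + 1e-9:
            raise ValueError(f"class proportions sum to {total:.3f} > 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        lo, hi = self.enrichment_factor_range
        if lo <= 1 or hi < lo:
            raise ValueError("enrichment factors must exceed 1")
        if self.count_model not in ("poisson", "nb"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        if len(self.stage_labels) < 2:
            raise ValueError("need at least 2 stages")

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)


@dataclass
class SimTruth:
    """Planted ground truth emitted by :func:`generate_truth`."""

    config: SimConfig
    #: per-gene metadata: transcript_id, chrom, strand, coding,
    #: class_label, corr_sign, dmr_category
    genes: pd.DataFrame
    #: gene x stage methylation schedule in WT
    presence: pd.DataFrame
    #: gene x stage true enrichment factor in WT (1.0 where absent)
    factors: pd.DataFrame
    #: KO truth at the first stage
    ko_presence: pd.Series
    ko_factor: pd.Series
    #: gene x stage true expression (FPKM scale)
    expression: pd.DataFrame
    #: one planted peak interval per gene (decoy site for unmethylated
    #: genes): genomic and transcript coordinates plus region label
    peaks: pd.DataFrame
    transcripts: list[TranscriptModel]
    reference: dict[str, TranscriptModel]

    def write_gtf(self, path: str) -> None:
        write_gtf(self.transcripts, path)


def _scan_adapter(seq: str, adapter: str, max_mismatch: int) -> Optional[int]:
    # independent minimal scan (full-length matches only), used to keep the
    # planted truth unambiguous; deliberately separate from the
    # preprocessing implementation under test
    m = len(adapter)
    for i in range(len(seq) - m + 1):
        mm = sum(1 for a, b in zip(seq[i:i + m], adapter) if a != b or a == "N")
        if mm <= max_mismatch:
            return i
    return None


def _split_lengths(rng: np.random.Generator, total: int, n: int,
                   minimum: int) -> list[int]:
    """Split ``total`` into ``n`` parts each >= minimum."""
    if total < n * minimum:
        n = max(1, total // minimum)
    if n == 1:
        return [total]
    budget = total - n * minimum
    cuts = np.sort(rng.integers(0, budget + 1, n - 1))
    parts, prev = [], 0
    for c in list(cuts) + [budget]:
        parts.append(minimum + (int(c) - prev))
        prev = int(c)
    return parts


def _make_gene_models(rng: np.random.Generator, cfg: SimConfig):
    """Lay out genes along one synthetic chromosome."""
    transcripts: list[TranscriptModel] = []
    rows = []
    cursor = 1000
    chrom = "chrS1"
    for g in range(cfg.n_genes):
        gene_id = f"G{g:05d}"
        tx_id = f"{gene_id}.t1"
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() >= cfg.noncoding_fraction
        if coding:
            utr5 = int(rng.integers(100, 301))
            cds = 3 * int(rng.integers(100, 501))
            utr3 = int(rng.integers(200, 601))
            L = utr5 + cds + utr3
        else:
            L = int(rng.integers(600, 2001))
            utr5 = cds = utr3 = 0
        n_exons = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
        exon_lens = _split_lengths(rng, L, n_exons, 400)
        exons, pos = [], cursor
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el + (int(rng.integers(200, 801)) if k < len(exon_lens) - 1 else 0)
        if coding:
            tx = TranscriptModel(gene_id, tx_id, chrom, strand, tuple(exons),
                                 cds_start=utr5, cds_end=utr5 + cds)
        else:
            tx = TranscriptModel(gene_id, tx_id, chrom, strand, tuple(exons))
        transcripts.append(tx)
        if rng.random() < cfg.multi_transcript_fraction:
            # a strictly shorter second isoform to exercise longest-transcript
            # selection
            if len(exons) > 1:
                alt_exons = tuple(exons[:-1])
            else:
                s, e = exons[0]
                alt_exons = ((s, s + max(400, int((e - s) * 0.6))),)
            transcripts.append(TranscriptModel(gene_id, f"{gene_id}.t2",
                                               chrom, strand, alt_exons))
        cursor = exons[-1][1] + int(rng.integers(500, 1501))
        rows.append({"gene_id": gene_id, "transcript_id": tx_id,
                     "chrom": chrom, "strand": strand, "coding": coding,
                     "length": L})
    genes = pd.DataFrame(rows).set_index("gene_id")
    return transcripts, genes


def _plant_peak(rng: np.random.Generator, tx: TranscriptModel,
                cfg: SimConfig):
    """Choose one peak interval on a transcript, within a single exon."""
    lo, hi = cfg.peak_length_range
    length = int(rng.integers(lo, hi + 1))
    if tx.is_coding:
        part = partition_regions(tx)
        labels = list(REGION_WEIGHTS)
        weights = np.array([REGION_WEIGHTS[l] for l in labels])
        spans = part.as_dict()
        avail = np.array([1.0 if spans[l][1] - spans[l][0] > 0 else 0.0
                          for l in labels])
        w = weights * avail
        label = str(rng.choice(labels, p=w / w.sum()))
        r0, r1 = spans[label]
    else:
        part = None
        r0, r1 = 0, tx.total_length
    mid_t = int(rng.integers(r0, r1))
    g_mid = tx.transcript_to_genomic(mid_t)
    # clamp to the exon holding the midpoint so the peak stays contiguous
    for es, ee in tx.exons:
        if es <= g_mid < ee:
            gstart = max(es, g_mid - length // 2)
            gend = min(ee, gstart + length)
            gstart = max(es, gend - length)
            break
    t_a = tx.genomic_to_transcript(gstart)
    t_b = tx.genomic_to_transcript(gend - 1)
    t0, t1 = min(t_a, t_b), max(t_a, t_b) + 1
    final_mid = tx.genomic_to_transcript((gstart + gend) // 2)
    if part is not None:
        label = label_position(part, final_mid)
    else:
        label = None
    return gstart, gend, t0, t1, label


def generate_truth(config: SimConfig) -> SimTruth:
    """Generate annotation plus planted methylation/expression truth.

    Deterministic given ``config.seed``: the same config yields a
    byte-identical annotation and truth tables.
    """
    rng = np.random.default_rng(config.seed)
    stages = list(config.stage_labels)
    S = len(stages)
    transcripts, genes = _make_gene_models(rng, config)
    reference = select_reference_transcript(transcripts)
    n = len(genes)

    # ---- methylation classes -------------------------------------------
    class_names = (["CMR"] + [f"SMR:{s}" for s in stages]
                   + ["switching", "unmethylated"])
    probs = ([config.cmr_fraction]
             + [config.smr_fraction_each] * S
             + [config.switching_fraction])
    probs.append(max(0.0, 1.0 - sum(probs)))
    labels = rng.choice(len(class_names), size=n, p=np.array(probs) / sum(probs))
    genes["class_label"] = [class_names[i] for i in labels]

    presence = np.zeros((n, S), dtype=bool)
    for i, lab in enumerate(genes["class_label"]):
        if lab == "CMR":
            presence[i, :] = True
        elif lab.startswith("SMR:"):
            presence[i, stages.index(lab.split(":", 1)[1])] = True
        elif lab == "switching":
            pat = SWITCH_PATTERNS[int(rng.integers(len(SWITCH_PATTERNS)))]
            if S == 4:
                presence[i, :] = np.array(pat, dtype=bool)
            else:  # generic: one change point, not first/last-only
                cut = int(rng.integers(1, S))
                start_on = bool(rng.integers(2))
                presence[i, :cut] = start_on
                presence[i, cut:] = not start_on
    presence_df = pd.DataFrame(presence, index=genes.index, columns=stages)

    # ---- enrichment factors and expression -----------------------------
    f_lo, f_hi = config.enrichment_factor_range
    base_factor = rng.uniform(f_lo, f_hi, size=n)
    factors = np.where(presence, base_factor[:, None], 1.0)
    expression = np.exp(rng.normal(np.log(20.0), 0.6, size=n))[:, None] \
        * np.exp(rng.normal(0.0, 0.25, size=(n, S)))

    # expression-coupled CMR genes
    genes["corr_sign"] = None
    cmr_idx = np.flatnonzero((genes["class_label"] == "CMR").to_numpy())
    n_corr = int(round(config.corr_fraction * len(cmr_idx)))
    corr_idx = rng.choice(cmr_idx, size=n_corr, replace=False) if n_corr else []
    for j, i in enumerate(corr_idx):
        top = rng.uniform(0.8 * f_hi, f_hi)
        traj = np.linspace(f_lo, top, S)
        if rng.random() < 0.5:
            traj = traj[::-1]
        factors[i, :] = traj
        # coupled genes span a broad expression range, so the 4-point
        # Pearson screen is exercised both where counting noise is
        # negligible and where it attenuates r below the cutoff
        e_base = np.exp(rng.normal(np.log(60.0), 0.5))
        sign = "+" if j % 2 == 0 else "-"
        genes.iloc[i, genes.columns.get_loc("corr_sign")] = sign
        if sign == "+":
            expression[i, :] = e_base * traj / traj.mean()
        else:
            anti = (traj.min() + traj.max()) - traj
            expression[i, :] = e_base * anti / anti.mean()

    # ---- knockout perturbation at the first stage ----------------------
    genes["dmr_category"] = "unchanged"
    ko_presence = presence_df[stages[0]].copy()
    # note: copy() — the Series must not alias the WT factor matrix
    ko_factor = pd.Series(factors[:, 0].copy(), index=genes.index, dtype=float)
    u = rng.random(n)
    for i, gid in enumerate(genes.index):
        if genes["corr_sign"].iloc[i] is not None:
            continue  # keep planted trajectories intact
        if presence[i, 0]:
            if u[i] < config.dmr_hyper_fraction:
                wt_f = rng.uniform(3.0, 4.0)
                factors[i, 0] = wt_f
                ko_factor.iloc[i] = wt_f * 4.0
                genes.iloc[i, genes.columns.get_loc("dmr_category")] = "hyper"
            elif u[i] < config.dmr_hyper_fraction + config.dmr_hypo_fraction:
                wt_f = rng.uniform(8.0, 10.0)
                factors[i, 0] = wt_f
                ko_factor.iloc[i] = wt_f / 4.0
                genes.iloc[i, genes.columns.get_loc("dmr_category")] = "hypo"
            elif u[i] < (config.dmr_hyper_fraction + config.dmr_hypo_fraction
                         + config.dmr_loss_fraction):
                ko_presence.iloc[i] = False
                ko_factor.iloc[i] = 1.0
                genes.iloc[i, genes.columns.get_loc("dmr_category")] = "loss"
            else:
                ko_factor.iloc[i] = factors[i, 0]
        else:
            if u[i] < config.dmr_gain_fraction:
                ko_presence.iloc[i] = True
                ko_factor.iloc[i] = rng.uniform(6.0, 10.0)
                genes.iloc[i, genes.columns.get_loc("dmr_category")] = "gain"
            else:
                ko_factor.iloc[i] = 1.0
    factors_df = pd.DataFrame(factors, index=genes.index, columns=stages)
    expr_df = pd.DataFrame(expression, index=genes.index, columns=stages)

    # ---- planted peak sites --------------------------------------------
    peak_rows = []
    for gid in genes.index:
        tx = reference[gid]
        gstart, gend, t0, t1, label = _plant_peak(rng, tx, config)
        peak_rows.append({
            "gene_id": gid, "peak_id": f"{gid}_pk", "chrom": tx.chrom,
            "start": gstart, "end": gend, "strand": tx.strand,
            "t_start": t0, "t_end": t1, "region_label": label,
        })
    peaks = pd.DataFrame(peak_rows).set_index("peak_id")

    return SimTruth(config=config, genes=genes, presence=presence_df,
                    factors=factors_df, ko_presence=ko_presence,
                    ko_factor=ko_factor, expression=expr_df, peaks=peaks,
                    transcripts=transcripts, reference=reference)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass
class SimCounts:
    """Per-sample library totals and per-region counts."""

    #: sample_id -> (ip_total, input_total)
    libstats: pd.DataFrame
    #: rows: peak_id, gene_id, sample_id, A (IP), D (input), C (length)
    peak_counts: pd.DataFrame
    #: rows: gene_id, transcript_id, sample_id, input_count, length
    transcript_counts: pd.DataFrame
    samples: list[str]

    def counts_for(self, sample_id: str) -> pd.DataFrame:
        return self.peak_counts[self.peak_counts["sample_id"] == sample_id]


def sample_ids(config: SimConfig) -> list[str]:
    """One library pair per stage for WT, plus KO at the first stage."""
    ids = [f"{s}_WT" for s in config.stage_labels]
    if "KO" in config.conditions:
        ids.append(f"{config.stage_labels[0]}_KO")
    return ids


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 config: SimConfig) -> np.ndarray:
    mu = np.maximum(mu, 0.0)
    if config.count_model == "poisson":
        return rng.poisson(mu)
    r = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def simulate_counts(truth: SimTruth, config: Optional[SimConfig] = None,
                    seed: Optional[int] = None) -> SimCounts:
    """Draw per-peak IP/input counts and per-transcript input counts.

    Input counts on a region of length C for a gene with expression e are
    Poisson with mean e * E * C / 1e9 (the FPKM identity inverted), so the
    measured input FPKM is unbiased for e.  IP counts multiply that rate by
    the planted enrichment factor (1 where unmethylated) and use the IP
    library total B.  Scaling all counts and totals by a common k leaves
    every enrichment score unchanged.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    stages = list(config.stage_labels)
    samples = sample_ids(config)
    gene_order = truth.genes.index
    e_all = truth.expression.loc[gene_order]
    C = (truth.peaks["end"] - truth.peaks["start"]).to_numpy(float)
    tx_len = np.array([truth.reference[g].total_length for g in gene_order],
                      dtype=float)

    lib_rows, pk_frames, tx_frames = [], [], []
    for sid in samples:
        stage, cond = sid.rsplit("_", 1)
        B = float(np.round(config.mean_depth * rng.uniform(0.85, 1.15)))
        E = float(np.round(config.mean_depth * rng.uniform(0.85, 1.15)))
        e = e_all[stage].to_numpy(float)
        if cond == "KO":
            f = truth.ko_factor.loc[gene_order].to_numpy(float)
        else:
            f = truth.factors.loc[gene_order, stage].to_numpy(float)
        mu_D = e * E * C / 1e9
        mu_A = f * e * B * C / 1e9
        D = _draw_counts(rng, mu_D, config)
        A = _draw_counts(rng, mu_A, config)
        pk_frames.append(pd.DataFrame({
            "peak_id": truth.peaks.index, "gene_id": truth.peaks["gene_id"].to_numpy(),
            "sample_id": sid, "A": A, "D": D, "C": C.astype(int)}))
        T = _draw_counts(rng, e * E * tx_len / 1e9, config)
        tx_frames.append(pd.DataFrame({
            "gene_id": gene_order,
            "transcript_id": [truth.reference[g].transcript_id for g in gene_order],
            "sample_id": sid, "input_count": T, "length": tx_len.astype(int)}))
        lib_rows.append({"sample_id": sid, "ip_total": B, "input_total": E})

    return SimCounts(
        libstats=pd.DataFrame(lib_rows).set_index("sample_id"),
        peak_counts=pd.concat(pk_frames, ignore_index=True),
        transcript_counts=pd.concat(tx_frames, ignore_index=True),
        samples=samples,
    )


def simulate_reads(truth: SimTruth, sample_id: str,
                   depth_scale: float = 1.0,
                   seed: Optional[int] = None) -> dict[str, pd.DataFrame]:
    """Generate BED6-style read intervals for one sample (IP and input).

    Reads are contiguous intervals of ``config.read_length`` nt placed
    within single exons; IP libraries add factor-proportional extra reads
    inside the planted peak.  Intended for read-level tests at small n.
    Returns ``{"ip": df, "input": df, "ip_total": float, "input_total": float}``
    with BED6 columns chrom/start/end/name/score/strand.
    """
    config = truth.config
    stage, cond = sample_id.rsplit("_", 1)
    rng = np.random.default_rng(
        (config.seed + 7919 * (1 + sample_ids(config).index(sample_id)))
        if seed is None else seed)
    B = E = config.mean_depth * depth_scale
    rl = config.read_length
    rows_ip, rows_in = [], []

    def _place(n_reads, lo, hi, out, prefix, chrom, strand):
        if n_reads <= 0:
            return
        span = hi - lo
        if span <= rl:
            starts = np.full(n_reads, lo)
            ends = np.full(n_reads, hi)
        else:
            starts = rng.integers(lo, hi - rl, n_reads)
            ends = starts + rl
        for k, (s, e) in enumerate(zip(starts, ends)):
            out.append((chrom, int(s), int(e), f"{prefix}_{len(out)}", 0, strand))

    for gid in truth.genes.index:
        tx = truth.reference[gid]
        e_g = float(truth.expression.loc[gid, stage])
        if cond == "KO":
            f = float(truth.ko_factor.loc[gid])
        else:
            f = float(truth.factors.loc[gid, stage])
        pk = truth.peaks[truth.peaks["gene_id"] == gid].iloc[0]
        for es, ee in tx.exons:
            mu_bg = e_g * E * (ee - es) / 1e9
            _place(rng.poisson(mu_bg), es, ee, rows_in, f"in_{gid}",
                   tx.chrom, tx.strand)
            _place(rng.poisson(e_g * B * (ee - es) / 1e9), es, ee, rows_ip,
                   f"ip_{gid}", tx.chrom, tx.strand)
        extra = rng.poisson((f - 1.0) * e_g * B * (pk["end"] - pk["start"]) / 1e9)
        _place(extra, int(pk["start"]), int(pk["end"]), rows_ip,
               f"ipk_{gid}", tx.chrom, tx.strand)

    cols = ["chrom", "start", "end", "name", "score", "strand"]
    return {"ip": pd.DataFrame(rows_ip, columns=cols),
            "input": pd.DataFrame(rows_in, columns=cols),
            "ip_total": float(B), "input_total": float(E)}


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

ADAPTER = "AGATCGGAAG"
_BASES = np.array(list("ACGT"))


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    if n_sub == 0:
        return seq
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for p in pos:
        options = [b for b in "ACGT" if b != chars[p]]
        chars[p] = options[int(rng.integers(3))]
    return "".join(chars)


def simulate_fastq(n_reads: int,
                   adapter_rate: float = 0.5,
                   seed: int = 0,
                   read_length: int = 100,
                   mismatch_weights: Sequence[float] = (0.5, 0.3, 0.2),
                   three_mismatch_rate: float = 0.0,
                   low_quality_tail_rate: float = 0.2,
                   out_fastq: Optional[str] = None):
    """Generate reads with adapters planted at recorded offsets.

    A fraction ``adapter_rate`` of reads embeds the adapter (with 0-2
    substitutions, mixed per ``mismatch_weights``) at a recorded offset;
    independently, ``three_mismatch_rate`` of reads embeds a 3-substitution
    copy that must NOT be trimmed under the at-most-two-mismatches rule.
    Backgrounds are rejection-sampled so no spurious <=2-mismatch adapter
    occurrence exists, keeping the planted truth unambiguous.

    Returns ``(reads, truth)`` where reads are :class:`~epitempo.preprocess.Read`
    objects and truth is a DataFrame (read_id, adapter_offset, n_mismatch;
    offset -1 where nothing <=2-mismatch was planted).  Optionally writes a
    Phred+33 FASTQ.
    """
    from .preprocess import Read  # local import to avoid a cycle at module load

    if not 0 <= adapter_rate <= 1:
        raise ValueError("adapter_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    reads, rows = [], []
    mm_w = np.asarray(mismatch_weights, float)
    mm_w = mm_w / mm_w.sum()
    for i in range(n_reads):
        rid = f"r{i:06d}"
        plant2 = rng.random() < adapter_rate
        plant3 = (not plant2) and rng.random() < three_mismatch_rate
        while True:
            seq = "".join(rng.choice(_BASES, size=read_length))
            offset, n_mm = -1, 0
            if plant2:
                n_mm = int(rng.choice(3, p=mm_w))
                offset = int(rng.integers(40, read_length - len(ADAPTER) + 1))
                ins = _mutate(rng, ADAPTER, n_mm)
                seq = seq[:offset] + ins + seq[offset + len(ADAPTER):]
                if _scan_adapter(seq, ADAPTER, 2) == offset:
                    break
            elif plant3:
                offset3 = int(rng.integers(40, read_length - len(ADAPTER) + 1))
                ins = _mutate(rng, ADAPTER, 3)
                seq = seq[:offset3] + ins + seq[offset3 + len(ADAPTER):]
                if _scan_adapter(seq, ADAPTER, 2) is None:
                    offset, n_mm = -1, 3
                    break
            else:
                if _scan_adapter(seq, ADAPTER, 2) is None:
                    break
        qual = np.clip(np.round(rng.normal(38, 2, read_length)), 2, 40).astype(int)
        if rng.random() < low_quality_tail_rate:
            tail = int(rng.integers(3, 15))
            qual[-tail:] = rng.integers(2, 20, tail)
        reads.append(Read(rid, seq, tuple(int(q) for q in qual)))
        rows.append({"read_id": rid, "adapter_offset": offset,
                     "n_mismatch": n_mm if (plant2 or plant3) else 0})
    truth = pd.DataFrame(rows).set_index("read_id")
    if out_fastq:
        with open(out_fastq, "w") as fh:
            for r in reads:
                qstr = "".join(chr(q + 33) for q in r.qualities)
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{qstr}\n")
    return reads, truth


# ---------------------------------------------------------------------------
# annotation output
# ---------------------------------------------------------------------------

def write_gtf(transcripts: Sequence[TranscriptModel], path: str) -> None:
    """Write exon and CDS features (GTF, 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for s, e in t.exons:
                fh.write("\t".join(map(str, [
                    t.chrom, "epitempo_sim", "exon", s + 1, e, ".",
                    t.strand, ".", attrs])) + "\n")
            if t.is_coding:
                for s, e in t.transcript_interval_to_genomic_blocks(
                        t.cds_start, t.cds_end):
                    fh.write("\t".join(map(str, [
                        t.chrom, "epitempo_sim", "CDS", s + 1, e, ".",
                        t.strand, "0", attrs])) + "\n")
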