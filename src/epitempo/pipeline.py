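"""End-to-end orchestration of the temporal methylation analysis.

The central entry point is :func:`run_count_analysis`, which takes a
candidate peak table, per-sample IP/input counts and library totals and
produces: per-sample quantified and retained peaks, the merged cross-stage
atlas with ON/OFF switches, CMR/SMR classes, metagene summaries,
WT-vs-KO differential methylation, and the methylation-expression
correlation screen.  :func:`run_pipeline` wraps it with config handling
and TSV/report output, either over a synthetic dataset generated in-run
or over user-provided tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import expression as expr_mod
from . import metagene as meta_mod
from . import quant as quant_mod
from . import temporal as temp_mod
from .io import write_table
from .simulate import SimConfig, SimTruth, SimCounts, generate_truth, \
    simulate_counts
from .transcripts import TranscriptModel

__all__ = ["RunConfig", "AnalysisResult", "quantify_samples",
           "run_count_analysis", "run_pipeline"]


@dataclass
class RunConfig:
    """Run-level configuration; thresholds default to the standard values."""

    out_dir: str = "epitempo_out"
    stages: tuple[str, ...] = ("P7", "P14", "P21", "P60")
    conditions: tuple[str, ...] = ("WT", "KO")
    fdr_threshold: float = quant_mod.FDR_THRESHOLD
    ip_fpkm_threshold: float = quant_mod.IP_FPKM_THRESHOLD
    enrichment_threshold: float = quant_mod.ENRICHMENT_THRESHOLD
    seed: int = 0
    #: synthetic mode: generate the dataset in-run
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    #: file mode inputs (used when simulate is False)
    annotation: Optional[str] = None
    peak_counts: Optional[str] = None
    libstats: Optional[str] = None
    transcript_counts: Optional[str] = None
    peaks: Optional[str] = None

    def __post_init__(self):
        if len(self.stages) < 2:
            raise ValueError("need at least 2 stages")
        for name in ("fdr_threshold", "ip_fpkm_threshold",
                     "enrichment_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Parse a key=value config file (''#'' comments allowed)."""
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key in ("stages", "conditions"):
                    kwargs[key] = tuple(v.strip() for v in val.split(","))
                elif key == "seed":
                    kwargs[key] = int(val)
                elif key == "simulate":
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                elif key.endswith("_threshold"):
                    kwargs[key] = float(val)
                elif key.startswith("sim."):
                    sim_kwargs = kwargs.setdefault("_sim", {})
                    sub = key[4:]
                    sim_kwargs[sub] = (int(val) if sub in ("n_genes", "seed")
                                       else float(val))
                else:
                    kwargs[key] = val
        sim_kwargs = kwargs.pop("_sim", {})
        cfg = cls(**kwargs)
        if sim_kwargs:
            cfg.sim = SimConfig(**sim_kwargs)
        return cfg


@dataclass
class AnalysisResult:
    quant: pd.DataFrame           # all candidate peaks x samples, quantified
    retained: pd.DataFrame        # retained subset
    filter_tallies: dict
    merged: pd.DataFrame          # cross-stage atlas with presence columns
    switches: pd.DataFrame
    classes: pd.DataFrame
    class_tally: dict
    region_counts: pd.DataFrame   # per stage x five regions
    profile: pd.DataFrame         # 300-bin metagene profile (all stages)
    dmr: pd.DataFrame
    rna_gain_loss: pd.DataFrame
    fpkm: pd.DataFrame
    meth_levels: pd.DataFrame
    correlation: pd.DataFrame
    correlation_tally: dict
    report: str


def quantify_samples(peaks: pd.DataFrame, counts: pd.DataFrame,
                     libstats: pd.DataFrame,
                     external_fdr: Optional[pd.Series] = None,
                     ) -> pd.DataFrame:
    """Quantify every candidate peak in every sample.

    ``peaks`` is indexed by peak_id with chrom/start/end/strand/gene_id;
    ``counts`` has rows peak_id/sample_id/A/D/C; ``libstats`` is indexed
    by sample_id with ip_total/input_total.  The per-sample significance
    is a one-sided binomial test of the IP/input split (BH-adjusted per
    sample) unless an external peak-caller FDR is supplied.
    """
    frames = []
    for sid, sub in counts.groupby("sample_id", sort=True):
        sub = sub.copy()
        B = float(libstats.loc[sid, "ip_total"])
        E = float(libstats.loc[sid, "input_total"])
        if external_fdr is not None:
            sub["fdr"] = external_fdr.reindex(sub["peak_id"]).to_numpy()
        else:
            p = quant_mod.region_enrichment_pvalues(
                sub["A"].to_numpy(), sub["D"].to_numpy(), B, E)
            sub["p"] = p
            sub["fdr"] = multipletests(p, method="fdr_bh")[1]
        qs = [quant_mod.quantify_peak(a, d, c, B, E)
              for a, d, c in zip(sub["A"], sub["D"], sub["C"])]
        sub["ip_fpkm"] = [q.ip_fpkm for q in qs]
        sub["input_fpkm"] = [q.input_fpkm for q in qs]
        sub["enrichment"] = [q.enrichment for q in qs]
        sub["enrichment_defined"] = [q.enrichment_defined for q in qs]
        frames.append(sub)
    quant = pd.concat(frames, ignore_index=True)
    coords = peaks[["chrom", "start", "end", "strand"]]
    quant = quant.merge(coords, left_on="peak_id", right_index=True,
                        how="left")
    return quant


def run_count_analysis(peaks: pd.DataFrame, counts: pd.DataFrame,
                       libstats: pd.DataFrame,
                       reference: dict[str, TranscriptModel],
                       transcript_counts: Optional[pd.DataFrame] = None,
                       stages: tuple[str, ...] = ("P7", "P14", "P21", "P60"),
                       ko_stage: Optional[str] = None,
                       config: Optional[RunConfig] = None,
                       external_fdr: Optional[pd.Series] = None,
                       ) -> AnalysisResult:
    """Run the full comparative analysis over count tables."""
    config = config or RunConfig(stages=tuple(stages))
    stages = list(stages)
    quant = quantify_samples(peaks, counts, libstats, external_fdr)
    retained, tallies = quant_mod.filter_peaks(
        quant, config.fdr_threshold, config.ip_fpkm_threshold,
        config.enrichment_threshold)

    wt_samples = [f"{s}_WT" for s in stages]
    wt_retained = retained[retained["sample_id"].isin(wt_samples)].copy()
    wt_retained["stage"] = wt_retained["sample_id"].str.rsplit(
        "_", n=1).str[0]
    merged = temp_mod.merge_peaks_across_samples(
        wt_retained, sample_col="stage", samples=stages)
    switches = temp_mod.detect_switches(merged, stages)
    presence = temp_mod.rna_presence_matrix(wt_retained, stages)
    classes, class_tally = temp_mod.classify_cmr_smr(presence)

    # metagene over all WT retained peaks, plus per-stage region counts
    assigned = meta_mod.assign_peaks(wt_retained, reference)
    profile = meta_mod.metagene_distribution(assigned, reference)
    region_rows = []
    for stage in stages:
        sub = assigned[assigned["stage"] == stage]
        series, _ = meta_mod.count_region_peaks(sub, reference)
        region_rows.append(series.rename(stage))
    region_counts = pd.DataFrame(region_rows)

    # WT vs KO differential methylation at the KO stage
    dmr = pd.DataFrame(columns=["gene_id", "score_x", "score_y", "p",
                                "log2fc", "category", "fdr"])
    gain_loss = pd.DataFrame(columns=["gene_id", "category"])
    if ko_stage is not None:
        sid_wt, sid_ko = f"{ko_stage}_WT", f"{ko_stage}_KO"
        if sid_ko in set(quant["sample_id"]):
            def _cond_frame(sid):
                sub = quant[quant["sample_id"] == sid].set_index("peak_id")
                sub = sub.assign(retained=(
                    (sub["fdr"] < config.fdr_threshold)
                    & (sub["ip_fpkm"] > config.ip_fpkm_threshold)
                    & (sub["enrichment"] > config.enrichment_threshold)))
                return sub
            ko_f, wt_f = _cond_frame(sid_ko), _cond_frame(sid_wt)
            dmr = temp_mod.detect_dmrs(
                ko_f, wt_f,
                (float(libstats.loc[sid_ko, "ip_total"]),
                 float(libstats.loc[sid_ko, "input_total"])),
                (float(libstats.loc[sid_wt, "ip_total"]),
                 float(libstats.loc[sid_wt, "input_total"])))
            gain_loss = temp_mod.rna_gain_loss(
                set(ko_f.loc[ko_f["retained"], "gene_id"]),
                set(wt_f.loc[wt_f["retained"], "gene_id"]))

    # methylation-expression correlation screen (WT)
    fpkm = pd.DataFrame()
    correlation = pd.DataFrame()
    corr_tally: dict = {}
    meth_levels = expr_mod.methylation_level_matrix(wt_retained, stages)
    if transcript_counts is not None:
        fpkm = expr_mod.fpkm_table(transcript_counts, libstats, stages)
        methylated = classes.index[classes["class_label"] != "unmethylated"]
        correlation, corr_tally = expr_mod.correlate_methylation_expression(
            meth_levels.loc[meth_levels.index.intersection(methylated)],
            fpkm)

    report = _format_report(stages, tallies, class_tally, switches,
                            region_counts, dmr, gain_loss, corr_tally)
    return AnalysisResult(
        quant=quant, retained=retained, filter_tallies=tallies,
        merged=merged, switches=switches, classes=classes,
        class_tally=class_tally, region_counts=region_counts,
        profile=profile, dmr=dmr, rna_gain_loss=gain_loss, fpkm=fpkm,
        meth_levels=meth_levels, correlation=correlation,
        correlation_tally=corr_tally, report=report)


def _format_report(stages, tallies, class_tally, switches, region_counts,
                   dmr, gain_loss, corr_tally) -> str:
    lines = ["# epitempo run report", ""]
    lines.append("## Peak retention")
    for k, v in tallies.items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("## Methylation classes")
    for k, v in class_tally.items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("## Switches per transition")
    if len(switches):
        pivot = switches.groupby(["transition", "direction"]).size()
        for (tr, d), v in pivot.items():
            lines.append(f"  {tr} {d}: {v}")
    lines.append("")
    lines.append("## Five-region peak counts per stage")
    lines.append(region_counts.to_string())
    lines.append("")
    if len(dmr):
        lines.append("## Differential methylation (KO vs WT)")
        for k, v in dmr["category"].value_counts().items():
            lines.append(f"  {k}: {v}")
        for k, v in gain_loss["category"].value_counts().items():
            lines.append(f"  RNA-level {k}: {v}")
        lines.append("")
    if corr_tally:
        lines.append("## Methylation-expression correlation")
        for k, v in corr_tally.items():
            lines.append(f"  {k}: {v}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Run the pipeline per config, writing TSV outputs plus a report.

    In synthetic mode (default) the dataset is generated in-run and truth
    tables are written next to the results.  Returns a dict with the
    AnalysisResult and (in synthetic mode) the SimTruth.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    if config.simulate:
        truth = generate_truth(config.sim)
        counts = simulate_counts(truth)
        peaks = truth.peaks.copy()
        reference = truth.reference
        transcript_counts = counts.transcript_counts
        peak_counts, libstats = counts.peak_counts, counts.libstats
        truth.write_gtf(os.path.join(config.out_dir, "annotation.gtf"))
        write_table(truth.genes, os.path.join(config.out_dir,
                                              "truth_genes.tsv"), index=True)
    else:
        from .io import read_table
        from .transcripts import parse_gtf, select_reference_transcript
        for name in ("annotation", "peak_counts", "libstats", "peaks"):
            if getattr(config, name) is None:
                raise ValueError(f"file mode requires config.{name}")
        truth = None
        models = parse_gtf(config.annotation)
        reference = select_reference_transcript(models)
        peaks = read_table(config.peaks).set_index("peak_id")
        peak_counts = read_table(config.peak_counts)
        libstats = read_table(config.libstats).set_index("sample_id")
        transcript_counts = (read_table(config.transcript_counts)
                             if config.transcript_counts else None)

    ko_stage = config.stages[0] if "KO" in config.conditions else None
    result = run_count_analysis(
        peaks, peak_counts, libstats, reference,
        transcript_counts=transcript_counts, stages=config.stages,
        ko_stage=ko_stage, config=config)

    out = config.out_dir
    write_table(result.quant, os.path.join(out, "peak_quant.tsv"))
    write_table(result.merged.reset_index(), os.path.join(out, "atlas.tsv"))
    write_table(result.switches, os.path.join(out, "switches.tsv"))
    write_table(result.classes.reset_index(names="rna_id"),
                os.path.join(out, "classes.tsv"))
    write_table(result.region_counts.reset_index(names="stage"),
                os.path.join(out, "region_counts.tsv"))
    write_table(result.profile, os.path.join(out, "metagene_profile.tsv"))
    write_table(result.dmr.reset_index(), os.path.join(out, "dmr.tsv"))
    write_table(result.rna_gain_loss, os.path.join(out, "rna_gain_loss.tsv"))
    if len(result.correlation):
        write_table(result.correlation.reset_index(),
                    os.path.join(out, "correlation.tsv"))
    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write(result.report)
    return {"result": result, "truth": truth}
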