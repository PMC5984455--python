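"""Recovery metrics against the planted truth of the synthetic generator.

These helpers score how well the analysis recovers what the generator
planted: methylation class labels, switch events, differential
methylation categories, metagene region placement, enrichment factors and
expression-coupling signs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import AnalysisResult
from .simulate import SimTruth

__all__ = ["class_f1", "switch_sensitivity", "dmr_category_accuracy",
           "region_recovery", "factor_score_spearman",
           "correlation_sign_recovery", "truth_switch_events"]


def class_f1(truth: SimTruth, result: AnalysisResult) -> float:
    """Macro F1 of CMR/SMR labels over genes truly in those classes.

    For each truth label (CMR and each SMR:<stage>) precision uses all
    genes predicted with that label, recall uses all genes truly in it;
    the macro average runs over truth labels that occur.
    """
    pred = result.classes["class_label"]
    truth_lab = truth.genes["class_label"]
    labels = [l for l in sorted(truth_lab.unique())
              if l == "CMR" or l.startswith("SMR:")]
    f1s = []
    for lab in labels:
        true_set = set(truth_lab.index[truth_lab == lab])
        pred_set = set(pred.index[pred == lab])
        tp = len(true_set & pred_set)
        prec = tp / len(pred_set) if pred_set else 0.0
        rec = tp / len(true_set) if true_set else 0.0
        f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
    return float(np.mean(f1s)) if f1s else float("nan")


def truth_switch_events(truth: SimTruth) -> set[tuple[str, str, str]]:
    """Planted (gene, transition, direction) events from the schedule."""
    stages = list(truth.presence.columns)
    events = set()
    mat = truth.presence.to_numpy(bool)
    for i, gene in enumerate(truth.presence.index):
        for j, (a, b) in enumerate(zip(stages, stages[1:])):
            if not mat[i, j] and mat[i, j + 1]:
                events.add((gene, f"{a}-{b}", "ON"))
            elif mat[i, j] and not mat[i, j + 1]:
                events.add((gene, f"{a}-{b}", "OFF"))
    return events


def switch_sensitivity(truth: SimTruth, result: AnalysisResult) -> float:
    """Fraction of planted switch events recovered by detect_switches."""
    planted = truth_switch_events(truth)
    if not planted:
        return float("nan")
    detected = set()
    for row in result.switches.itertuples():
        for gene in str(row.gene_id).split(","):
            detected.add((gene, row.transition, row.direction))
    return len(planted & detected) / len(planted)


def dmr_category_accuracy(truth: SimTruth, result: AnalysisResult) -> float:
    """Fraction of genes with a planted KO perturbation whose peak-level
    differential-methylation category is recovered exactly."""
    perturbed = truth.genes[truth.genes["dmr_category"]
                            .isin(["hyper", "hypo", "gain", "loss"])]
    if not len(perturbed):
        return float("nan")
    dmr = result.dmr
    gene_cat = {}
    for pid, row in dmr.iterrows():
        for gene in str(row["gene_id"]).split(","):
            gene_cat[gene] = row["category"]
    hits = sum(1 for gene, row in perturbed.iterrows()
               if gene_cat.get(gene) == row["dmr_category"])
    return hits / len(perturbed)


def region_recovery(truth: SimTruth, result: AnalysisResult) -> float:
    """Fraction of retained, assigned peaks landing in their planted
    five-region label."""
    from .metagene import assign_peaks
    from .transcripts import partition_regions, label_position

    planted = truth.peaks.set_index("gene_id")["region_label"]
    wt = result.retained[result.retained["sample_id"].str.endswith("_WT")]
    assigned = assign_peaks(wt, truth.reference)
    hits = total = 0
    parts = {}
    for row in assigned.itertuples():
        if not row.assigned or planted.get(row.gene_id) is None:
            continue
        t = truth.reference[row.gene_id]
        part = parts.setdefault(row.gene_id, partition_regions(t))
        total += 1
        if label_position(part, row.t_offset) == planted[row.gene_id]:
            hits += 1
    return hits / total if total else float("nan")


def factor_score_spearman(truth: SimTruth, result: AnalysisResult) -> float:
    """Spearman correlation of planted enrichment factor vs measured
    enrichment score over retained WT peaks at truly methylated
    gene-stages."""
    xs, ys = [], []
    for row in result.retained.itertuples():
        sid = row.sample_id
        if not sid.endswith("_WT"):
            continue
        stage = sid.rsplit("_", 1)[0]
        gene = row.gene_id
        if not bool(truth.presence.loc[gene, stage]):
            continue
        if not np.isfinite(row.enrichment):
            continue
        xs.append(float(truth.factors.loc[gene, stage]))
        ys.append(float(row.enrichment))
    if len(xs) < 3:
        return float("nan")
    return float(stats.spearmanr(xs, ys).statistic)


def expected_correlation_attenuation(truth: SimTruth) -> pd.Series:
    """Expected measured |r| per planted expression-coupled RNA.

    The planted trajectories are perfectly collinear, so the measured
    Pearson r is attenuated only by counting noise.  By the delta method
    the enrichment score at stage s has relative variance 1/E[A_s] +
    1/E[D_s] and the FPKM estimate 1/E[T_s]; with noise-to-signal ratios
    q_m and q_e (mean noise variance over trajectory variance) the
    expected r is 1 / sqrt((1 + q_m)(1 + q_e)).  Computed from planted
    means only — no drawn counts enter.
    """
    cfg = truth.config
    B = E = cfg.mean_depth
    C = (truth.peaks.set_index("gene_id")["end"]
         - truth.peaks.set_index("gene_id")["start"])
    out = {}
    for gid in truth.genes.index[truth.genes["corr_sign"].notna()]:
        f = truth.factors.loc[gid].to_numpy(float)
        e = truth.expression.loc[gid].to_numpy(float)
        c = float(C[gid])
        L = truth.reference[gid].total_length
        mu_A = f * e * B * c / 1e9
        mu_D = e * E * c / 1e9
        mu_T = e * E * L / 1e9
        q_m = np.mean(f ** 2 * (1 / mu_A + 1 / mu_D)) / np.var(f)
        q_e = np.mean(e ** 2 / mu_T) / np.var(e)
        out[gid] = 1.0 / np.sqrt((1 + q_m) * (1 + q_e))
    return pd.Series(out, dtype=float)


def correlation_sign_recovery(truth: SimTruth, result: AnalysisResult,
                              min_expected_r: Optional[float] = 0.98) -> float:
    """Fraction of planted expression-coupled RNAs recovered with the
    correct correlation sign.

    By default restricted to high-signal plants: those whose expected
    noise-attenuated |r| (see :func:`expected_correlation_attenuation`)
    stays >= 0.98, i.e. counting noise consumes at most half the margin
    between perfect collinearity and the 0.95 screening cutoff.  Pass
    ``min_expected_r=None`` to score all planted RNAs.
    """
    planted = truth.genes["corr_sign"].dropna()
    if min_expected_r is not None:
        r_exp = expected_correlation_attenuation(truth)
        planted = planted[r_exp.reindex(planted.index) >= min_expected_r]
    if not len(planted):
        return float("nan")
    pred = result.correlation["sign_class"] if len(result.correlation) else \
        pd.Series(dtype=object)
    name = {"+": "positive", "-": "negative"}
    hits = sum(1 for gene, sign in planted.items()
               if pred.get(gene) == name[sign])
    return hits / len(planted)
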