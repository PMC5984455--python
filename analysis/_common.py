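"""Shared setup for the analysis drivers: one deterministic synthetic
study (1,000 genes, 4 stages, WT + KO at P7) analyzed end to end."""

import os

from epitempo.pipeline import run_count_analysis
from epitempo.simulate import SimConfig, generate_truth, simulate_counts

SEED = 1
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def load_study():
    cfg = SimConfig(n_genes=1000, seed=SEED)
    truth = generate_truth(cfg)
    counts = simulate_counts(truth)
    result = run_count_analysis(
        truth.peaks, counts.peak_counts, counts.libstats, truth.reference,
        transcript_counts=counts.transcript_counts,
        stages=cfg.stage_labels, ko_stage="P7")
    return cfg, truth, counts, result


def results_path(name):
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)
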