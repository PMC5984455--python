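import numpy as np
import pytest

from epitempo import SimConfig, generate_truth, simulate_counts
from epitempo.pipeline import run_count_analysis


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_truth():
    """300-gene synthetic truth shared across tests."""
    return generate_truth(SimConfig(n_genes=300, seed=11))


@pytest.fixture(scope="session")
def small_counts(small_truth):
    return simulate_counts(small_truth)


@pytest.fixture(scope="session")
def small_result(small_truth, small_counts):
    return run_count_analysis(
        small_truth.peaks, small_counts.peak_counts, small_counts.libstats,
        small_truth.reference,
        transcript_counts=small_counts.transcript_counts,
        stages=small_truth.config.stage_labels, ko_stage="P7")


def random_transcripts(rng, n, allow_short_cds=True):
    """Random coding TranscriptModels, including short-CDS edge cases."""
    from epitempo.transcripts import TranscriptModel
    models = []
    for k in range(n):
        utr5 = int(rng.integers(0, 400))
        if allow_short_cds and k % 5 == 0:
            cds = 3 * int(rng.integers(1, 100))     # short CDS, windows collide
        else:
            cds = 3 * int(rng.integers(100, 500))
        utr3 = int(rng.integers(0, 500))
        L = utr5 + cds + utr3
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        bounds = np.sort(rng.choice(np.arange(1, L), size=n_ex - 1,
                                    replace=False)) if n_ex > 1 else []
        lens = np.diff([0, *bounds, L])
        exons, pos = [], int(rng.integers(0, 10000))
        for el in lens:
            exons.append((pos, pos + int(el)))
            pos += int(el) + int(rng.integers(50, 300))
        models.append(TranscriptModel(
            gene_id=f"g{k}", transcript_id=f"g{k}.t", chrom="chrT",
            strand=strand, exons=tuple(exons),
            cds_start=utr5, cds_end=utr5 + cds))
    return models
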