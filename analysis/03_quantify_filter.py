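"""Quantify every candidate peak in every library (ip FPKM, input FPKM,
enrichment score) and apply the three retention criteria; compare
enrichment-score distributions between stages by rank-sum test."""

import numpy as np
import pandas as pd

from _common import load_study, results_path
from epitempo.io import write_table
from epitempo.quant import compare_enrichment_distributions


def main():
    cfg, truth, counts, result = load_study()
    tally = pd.DataFrame(sorted(result.filter_tallies.items()),
                         columns=["metric", "value"])
    write_table(tally, results_path("peak_retention_tally.tsv"))
    print("Peak retention (FDR < 0.05, ip FPKM > 1, enrichment > 1.5):")
    print(tally.to_string(index=False))

    rows = []
    stages = list(cfg.stage_labels)
    ret = result.retained[np.isfinite(result.retained["enrichment"])]
    for a, b in zip(stages, stages[1:]):
        xa = ret.loc[ret["sample_id"] == f"{a}_WT", "enrichment"]
        xb = ret.loc[ret["sample_id"] == f"{b}_WT", "enrichment"]
        stat, p = compare_enrichment_distributions(xa, xb)
        rows.append({"comparison": f"{a} vs {b}", "n_x": len(xa),
                     "n_y": len(xb), "median_x": xa.median(),
                     "median_y": xb.median(), "ranksum_p": p})
    table = pd.DataFrame(rows)
    write_table(table, results_path("enrichment_distribution_tests.tsv"))
    print("\nStage-to-stage enrichment-score comparisons (Wilcoxon):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
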