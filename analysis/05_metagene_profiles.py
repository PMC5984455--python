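"""Where do peaks sit on transcripts?  Five-region counts per stage and
for stage-specific (SMR) peaks, plus the 100-bin metagene profile."""

import pandas as pd

import epitempo.evaluate as ev
from _common import load_study, results_path
from epitempo.io import write_table
from epitempo.metagene import assign_peaks, count_region_peaks


def main():
    cfg, truth, counts, result = load_study()
    write_table(result.region_counts.reset_index(names="stage"),
                results_path("region_counts_per_stage.tsv"))
    print("Five-region peak counts per stage (all retained WT peaks):")
    print(result.region_counts.to_string())

    # SMR-specific peaks: the retained peaks of each stage's SMRs
    smr_rows = []
    classes = result.classes["class_label"]
    for stage in cfg.stage_labels:
        smr_genes = set(classes.index[classes == f"SMR:{stage}"])
        sub = result.retained[
            (result.retained["sample_id"] == f"{stage}_WT")
            & result.retained["gene_id"].isin(smr_genes)]
        assigned = assign_peaks(sub, truth.reference)
        series, _ = count_region_peaks(assigned, truth.reference)
        smr_rows.append(series.rename(stage))
    smr_counts = pd.DataFrame(smr_rows)
    write_table(smr_counts.reset_index(names="stage"),
                results_path("region_counts_smr_peaks.tsv"))
    print("\nFive-region counts of stage-specific (SMR) peaks:")
    print(smr_counts.to_string())

    rec = ev.region_recovery(truth, result)
    print(f"\n{rec:.1%} of retained peaks land in their planted region.")
    write_table(result.profile, results_path("metagene_profile.tsv"))
    top = result.profile.nlargest(5, "count")[["bin", "segment", "percent"]]
    print("Top metagene bins by occupancy:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
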