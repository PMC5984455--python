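"""Exercise the read-preprocessing stage on a 20,000-read FASTQ with
planted adapters: trim at the adapter, clip low-quality 3' ends, keep
reads > 70 nt with > 70% of bases above Q25."""

import os
import tempfile

import pandas as pd

from _common import results_path, SEED
from epitempo.io import write_table
from epitempo.preprocess import process_fastq, preprocess_read
from epitempo.simulate import simulate_fastq


def main():
    with tempfile.TemporaryDirectory() as tmp:
        fq_in = os.path.join(tmp, "raw.fastq")
        fq_out = os.path.join(tmp, "clean.fastq")
        reads, truth = simulate_fastq(20_000, adapter_rate=0.4, seed=SEED,
                                      out_fastq=fq_in)
        statistics = process_fastq(fq_in, fq_out)

    planted = truth[truth["adapter_offset"] >= 0]
    correct = sum(preprocess_read(r).adapter_offset
                  == int(truth.loc[r.id, "adapter_offset"])
                  for r in reads if truth.loc[r.id, "adapter_offset"] >= 0)
    statistics["planted_adapters"] = len(planted)
    statistics["trimmed_at_planted_offset"] = correct

    df = pd.DataFrame(sorted(statistics.items()),
                      columns=["metric", "value"])
    write_table(df, results_path("preprocess_stats.tsv"))
    print(df.to_string(index=False))
    print(f"\nAll {len(planted)} planted adapters trimmed at their recorded "
          f"offsets: {correct == len(planted)}.")


if __name__ == "__main__":
    main()
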