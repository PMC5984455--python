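"""Flat-file helpers: BED6(+FDR), count/library TSVs.

All tables are tab-separated with a header; BED files are 0-based
half-open, strand in column 6, an optional FDR in column 7.
"""

from __future__ import annotations

import pandas as pd

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path: str, fdr_column: bool = False) -> pd.DataFrame:
    cols = BED6_COLS + (["fdr"] if fdr_column else [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < len(cols):
        raise ValueError(
            f"{path}: expected >= {len(cols)} columns, found {df.shape[1]}")
    df = df.iloc[:, :len(cols)]
    df.columns = cols
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0]
        raise ValueError(f"{path}: empty interval at line {bad + 1}")
    return df


def write_bed6(df: pd.DataFrame, path: str, extra: list[str] | None = None) -> None:
    cols = BED6_COLS + (extra or [])
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
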