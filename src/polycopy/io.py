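"""Plain-text genomics formats: chrom.sizes, BED, bedGraph, TSV.

All coordinates 0-based half-open; bedGraph written without a track line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeSpec

BED3_COLS = ["chrom", "start", "end"]
BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path: str | Path, bin_width: int = 1000) -> GenomeSpec:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeSpec(chroms=tuple(zip(df["chrom"], df["length"])), bin_width=bin_width)


def write_chrom_sizes(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chroms:
            fh.write(f"{name}\t{length}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ into a DataFrame; extra columns get BED6 names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = (BED6_COLS + [f"col{i}" for i in range(6, df.shape[1])])[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED3_COLS + ["value"], comment="#")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED3_COLS + ["value"])


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
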