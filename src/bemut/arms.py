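"""Autosomal chromosome-arm table (hg19 boundaries, centromeres excluded)."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_arm_table", "read_arm_table", "assign_arms", "genome_size_mb"]

_COLS = ["chrom", "arm", "start", "end", "length_mb"]


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["length_mb"] = (df["end"] - df["start"]) / 1e6
    if (df["end"] <= df["start"]).any():
        raise ValueError("arm with end <= start")
    # arms within a chromosome must not overlap
    for _, sub in df.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
            raise ValueError("overlapping arms within a chromosome")
    return df.reset_index(drop=True)


def load_arm_table() -> pd.DataFrame:
    """Packaged hg19 autosomal arm boundaries (0-based half-open)."""
    with resources.files("bemut").joinpath("data/arms_hg19.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return _finalize(df)


def read_arm_table(path) -> pd.DataFrame:
    """Read a BED-like arm table TSV: chrom, arm, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("chrom", "arm", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"arm table missing column(s): {missing}")
    return _finalize(df)


def genome_size_mb(arm_table: pd.DataFrame) -> float:
    return float(arm_table["length_mb"].sum())


def assign_arms(chrom: pd.Series, pos: pd.Series, arm_table: pd.DataFrame) -> pd.Series:
    """Map 1-based positions to arm labels like ``1p``; NaN if unmapped.

    Positions in centromeric gaps (or on chromosomes absent from the
    table) get NaN; callers report the dropped count.
    """
    out = pd.Series(np.nan, index=chrom.index, dtype=object)
    for c, sub in arm_table.groupby("chrom"):
        mask = chrom == c
        if not mask.any():
            continue
        p0 = pos[mask].to_numpy() - 1  # to 0-based
        lab = np.full(p0.shape, None, dtype=object)
        for row in sub.itertuples(index=False):
            inside = (p0 >= row.start) & (p0 < row.end)
            lab[inside] = f"{row.chrom}{row.arm}"
        out[mask] = lab
    return out
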