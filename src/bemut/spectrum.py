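"""Pyrimidine-strand normalization, 96-channel spectra and mutation loads.

Each SNV is referred to the pyrimidine of the mutated Watson-Crick pair:
six substitutions (C>A, C>G, C>T, T>A, T>C, T>G) by sixteen flanking-base
contexts give the 96 trinucleotide channels. Channel order is the
conventional one (substitution blocks in the order above; within a block
the 5' then 3' flank each run through A, C, G, T), so matrices line up
with external signature tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arms import assign_arms
from .catalog import FUNCTIONAL_CATEGORIES

__all__ = [
    "SUBSTITUTIONS",
    "CHANNELS",
    "SpectrumMatrix",
    "normalize_substitution",
    "channel_index",
    "build_spectrum",
    "mutation_load",
    "arm_density_table",
]

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: labels like ``A[C>A]A`` in the fixed channel order
CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

_CHANNEL_INDEX = {lab: i for i, lab in enumerate(CHANNELS)}


def _revcomp(s: str) -> str:
    return "".join(_COMPL[b] for b in reversed(s))


def normalize_substitution(ref: str, alt: str, context3: str) -> tuple[str, str]:
    """Return (substitution, pyrimidine-strand trinucleotide context).

    If ``ref`` is a purine the substitution and context are
    reverse-complemented so the mutated base reads as C or T.
    """
    if set(ref + alt + context3) - set(_BASES):
        raise ValueError(f"non-ACGT character in {(ref, alt, context3)!r}")
    if len(context3) != 3 or context3[1] != ref:
        raise ValueError(f"context3 {context3!r} not centred on ref {ref!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "GA":
        ref, alt, context3 = _COMPL[ref], _COMPL[alt], _revcomp(context3)
    return f"{ref}>{alt}", context3


def channel_index(ref: str, alt: str, context3: str) -> int:
    sub, ctx = normalize_substitution(ref, alt, context3)
    return _CHANNEL_INDEX[f"{ctx[0]}[{sub}]{ctx[2]}"]


@dataclass
class SpectrumMatrix:
    """Patients x 96 trinucleotide-substitution counts."""

    patients: list[str]
    counts: np.ndarray  # shape (n_patients, 96), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.patients), 96):
            raise ValueError("counts must be n_patients x 96")
        if (self.counts < 0).any():
            raise ValueError("negative spectrum count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.patients, columns=list(CHANNELS))

    def row(self, patient_id: str) -> np.ndarray:
        return self.counts[self.patients.index(patient_id)]

    def write(self, path) -> None:
        # 96 rows x patients, channel labels first column
        self.to_frame().T.rename_axis("channel").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "SpectrumMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(CHANNELS):
            raise ValueError("spectrum file channels out of order")
        return cls(patients=[str(c) for c in df.columns], counts=df.T.to_numpy())


def _channels_vectorized(df: pd.DataFrame) -> np.ndarray:
    """Channel index for every SNV row of a catalog frame."""
    key = df["context3"].astype(str) + ">" + df["alt"].astype(str)
    lut = {}
    for five in _BASES:
        for ref in _BASES:
            for alt in _BASES:
                if alt == ref:
                    continue
                for three in _BASES:
                    ctx = five + ref + three
                    lut[ctx + ">" + alt] = channel_index(ref, alt, ctx)
    return key.map(lut).to_numpy()


def build_spectrum(catalog: pd.DataFrame, meta: pd.DataFrame) -> SpectrumMatrix:
    """Count each patient's SNVs into the 96 channels; indels excluded."""
    patients = meta["patient_id"].astype(str).tolist()
    counts = np.zeros((len(patients), 96), dtype=np.int64)
    snv = catalog[catalog["mut_type"] == "SNV"]
    if len(snv):
        chan = _channels_vectorized(snv)
        pidx = snv["patient_id"].astype(str).map({p: i for i, p in enumerate(patients)})
        np.add.at(counts, (pidx.to_numpy(), chan), 1)
    return SpectrumMatrix(patients=patients, counts=counts)


def mutation_load(
    catalog: pd.DataFrame, meta: pd.DataFrame, which: str = "all"
) -> pd.DataFrame:
    """Per-patient mutation count and count per Mb of captured territory.

    ``which``: 'all' (SNV+indel), 'functional', 'snv' or 'indel'.
    """
    if (meta["target_mb"] <= 0).any():
        raise ValueError("target_mb must be > 0")
    if which == "all":
        sub = catalog
    elif which == "snv":
        sub = catalog[catalog["mut_type"] == "SNV"]
    elif which == "indel":
        sub = catalog[catalog["mut_type"] != "SNV"]
    elif which == "functional":
        sub = catalog[catalog["category"].isin(FUNCTIONAL_CATEGORIES)]
    else:
        raise ValueError(f"unknown which={which!r}")
    counts = sub.groupby("patient_id").size()
    out = meta[["patient_id", "target_mb"]].copy()
    out["count"] = out["patient_id"].map(counts).fillna(0).astype(int)
    out["load_per_mb"] = out["count"] / out["target_mb"]
    return out[["patient_id", "count", "load_per_mb"]]


def arm_density_table(
    catalog: pd.DataFrame, arm_table: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Per-(patient, arm) mutation density (mutations / Mb of arm).

    Returns (table, n_dropped) where n_dropped counts mutations that fell
    in no arm (centromeric gaps / unlisted chromosomes).
    """
    arm_labels = [f"{r.chrom}{r.arm}" for r in arm_table.itertuples(index=False)]
    arm_len = {f"{r.chrom}{r.arm}": r.length_mb for r in arm_table.itertuples(index=False)}
    arms = assign_arms(catalog["chrom"].astype(str), catalog["pos"], arm_table)
    mapped = arms.notna()
    n_dropped = int((~mapped).sum())
    counts = (
        pd.DataFrame({"patient_id": catalog.loc[mapped, "patient_id"], "arm": arms[mapped]})
        .groupby(["patient_id", "arm"])
        .size()
    )
    patients = meta["patient_id"].astype(str).tolist()
    idx = pd.MultiIndex.from_product([patients, arm_labels], names=["patient_id", "arm"])
    table = counts.reindex(idx, fill_value=0).rename("count").reset_index()
    table["length_mb"] = table["arm"].map(arm_len)
    table["density"] = table["count"] / table["length_mb"]
    return table, n_dropped
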