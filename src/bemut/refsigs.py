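"""Reference mutational signatures (synthetic stand-in set).

The packaged 96x30 matrix is a deterministic synthetic construction, not
the COSMIC v2 catalog: column S1 mimics the spontaneous-deamination
signature (C>T concentrated at NpCpG), column S17 mimics the
esophageal/gastric signature (T>G and T>C concentrated at CTT/NTT), and
the remaining columns are sparse Dirichlet draws with distinct modes.
Any user-supplied 96xK matrix in the same layout is a drop-in.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .spectrum import CHANNELS

__all__ = ["synthetic_reference_signatures", "load_reference_signatures"]


def synthetic_reference_signatures(n_signatures: int = 30, seed: int = 0) -> pd.DataFrame:
    """Deterministic synthetic 96 x K signature matrix (columns sum to 1)."""
    rng = np.random.default_rng(seed)
    n_channels = len(CHANNELS)
    W = np.zeros((n_channels, n_signatures))

    def chan(five, sub, three):
        return CHANNELS.index(f"{five}[{sub}]{three}")

    # S1-like: C>T at NpCpG, clock-like deamination of methylated cytosine
    s1 = np.full(n_channels, 0.1)
    for five in "ACGT":
        s1[chan(five, "C>T", "G")] += 6.0
    for five in "ACGT":
        for three in "ACT":
            s1[chan(five, "C>T", three)] += 0.8
    W[:, 0] = s1

    # S17-like: T>G transversions and T>C transitions at CTT-type contexts
    s17 = np.full(n_channels, 0.05)
    s17[chan("C", "T>G", "T")] += 10.0
    s17[chan("T", "T>G", "T")] += 3.0
    s17[chan("A", "T>G", "T")] += 1.5
    s17[chan("G", "T>G", "T")] += 1.5
    s17[chan("C", "T>C", "T")] += 4.0
    s17[chan("A", "T>C", "T")] += 1.0
    idx_s17 = 16  # position S17 in a COSMIC-like S1..S30 layout

    # remaining columns: sparse Dirichlet draws, each with its own modes
    for j in range(n_signatures):
        if j == 0:
            continue
        if j == idx_s17:
            W[:, j] = s17
            continue
        alpha = np.full(n_channels, 0.08)
        modes = rng.choice(n_channels, size=6, replace=False)
        alpha[modes] = 4.0
        W[:, j] = rng.dirichlet(alpha)
    W /= W.sum(axis=0, keepdims=True)
    cols = [f"S{j + 1}" for j in range(n_signatures)]
    return pd.DataFrame(W, index=list(CHANNELS), columns=cols)


def load_reference_signatures(path=None) -> pd.DataFrame:
    """Load a 96xK signature TSV (channel labels in the first column).

    Without ``path``, loads the packaged synthetic reference set.
    """
    if path is None:
        src = resources.files("bemut").joinpath(
            "data/reference_signatures_synthetic.tsv"
        )
        with src.open() as fh:
            df = pd.read_csv(fh, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CHANNELS):
        raise ValueError("signature file channels do not match the 96-channel order")
    sums = df.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError("signature columns must each sum to 1")
    return df / sums  # exact column-stochastic after file rounding
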