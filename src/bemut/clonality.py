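"""VAF-based clonality comparison in diploid-balanced territory.

In highly pure epithelium the variant allele frequency of a mutation in
a diploid, cnLOH-free region approximates half the prevalence of the
carrying clone, so the count of mutations above a VAF threshold measures
the burden carried by expanded (predominant) clones. Mutations inside
copy-altered or cnLOH segments are excluded first to avoid VAF
distortion by copy number.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .catalog import FUNCTIONAL_CATEGORIES
from .stats import TestResult, bh_adjust, kruskal_wallis

__all__ = [
    "filter_diploid",
    "count_high_vaf",
    "vaf_threshold_scan",
    "DEFAULT_THRESHOLDS",
]

#: default scan grid; the headline threshold 0.3 is one of its points
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


def filter_diploid(catalog: pd.DataFrame, segments: pd.DataFrame | None) -> pd.DataFrame:
    """Keep mutations outside every copy-altered/cnLOH segment.

    The unsegmented background is diploid-balanced (2 copies, minor 1).
    Patients with no segment data keep all their mutations, with a
    warning. Idempotent.
    """
    if segments is None or len(segments) == 0:
        if segments is None:
            warnings.warn("no segment data; retaining all mutations", stacklevel=2)
        return catalog.copy()
    altered = segments[segments["class"] != "diploid"]
    keep = np.ones(len(catalog), dtype=bool)
    pos0 = catalog["pos"].to_numpy() - 1
    chroms = catalog["chrom"].astype(str).to_numpy()
    pids = catalog["patient_id"].astype(str).to_numpy()
    for (pid, chrom), sub in altered.groupby(["patient_id", "chrom"]):
        sel = (pids == str(pid)) & (chroms == str(chrom))
        if not sel.any():
            continue
        p = pos0[sel]
        inside = np.zeros(len(p), dtype=bool)
        for s in sub.itertuples(index=False):
            inside |= (p >= s.start) & (p < s.end)
        k = keep[sel]
        k[inside] = False
        keep[sel] = k
    return catalog[keep].reset_index(drop=True)


def _select_which(catalog: pd.DataFrame, which: str) -> pd.DataFrame:
    snv = catalog[catalog["mut_type"] == "SNV"]
    functional = snv["category"].isin(FUNCTIONAL_CATEGORIES)
    if which == "functional":
        return snv[functional]
    if which == "nonfunctional":
        return snv[~functional]
    if which == "all":
        return snv
    raise ValueError(f"which must be 'functional', 'nonfunctional' or 'all', got {which!r}")


def count_high_vaf(
    catalog: pd.DataFrame,
    meta: pd.DataFrame,
    threshold: float,
    which: str = "functional",
) -> pd.DataFrame:
    """Per-patient counts of point mutations with VAF strictly above threshold.

    Missing-VAF mutations are excluded from numerator and denominator;
    the proportion is NaN for patients with no eligible mutations.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    sub = _select_which(catalog, which)
    sub = sub[sub["vaf"].notna()]
    n_total = sub.groupby("patient_id").size()
    n_above = sub[sub["vaf"] > threshold].groupby("patient_id").size()
    out = meta[["patient_id"]].copy()
    out["n_total"] = out["patient_id"].map(n_total).fillna(0).astype(int)
    out["n_above"] = out["patient_id"].map(n_above).fillna(0).astype(int)
    out["proportion_above"] = np.where(
        out["n_total"] > 0, out["n_above"] / out["n_total"].replace(0, 1), np.nan
    )
    out["threshold"] = threshold
    return out


def vaf_threshold_scan(
    catalog: pd.DataFrame,
    meta: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    which: str = "functional",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group comparison of high-VAF mutation counts across a threshold grid.

    Per threshold: Kruskal-Wallis on per-patient counts above threshold
    (raw) and on per-patient proportions (adjusted for total mutation
    number). Raw p-values are reported uncorrected (exploratory) with a
    BH-adjusted column alongside.
    """
    users = meta.loc[meta["nsaid_user"], "patient_id"]
    nonusers = meta.loc[~meta["nsaid_user"], "patient_id"]
    rows = []
    for thr in thresholds:
        tab = count_high_vaf(catalog, meta, float(thr), which=which).set_index("patient_id")
        cu, cn = tab.loc[users, "n_above"], tab.loc[nonusers, "n_above"]
        pu = tab.loc[users, "proportion_above"].dropna()
        pn = tab.loc[nonusers, "proportion_above"].dropna()
        raw = kruskal_wallis(cu, cn)
        prop = (
            kruskal_wallis(pu, pn)
            if len(pu) and len(pn)
            else TestResult(statistic=np.nan, p_value=1.0, n_used=0)
        )
        rows.append(
            {
                "threshold": float(thr),
                "median_user": float(cu.median()),
                "median_nonuser": float(cn.median()),
                "H": raw.statistic,
                "p_raw": raw.p_value,
                "p_proportion": prop.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["q_raw"], _ = bh_adjust(out["p_raw"].to_numpy(), fdr=alpha)
    out["significant"] = out["p_raw"] < alpha
    return out
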