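"""Pathway burden, per-gene burden, and pathway mutation diversity.

Mutations (SNVs and indels) within 1 kb of a gene are assigned to every
pathway containing that gene; a gene in several pathways increments each
of them (documented double counting). Burdens split into likely
functional vs presumed non-functional counts. Diversity per patient is
a Shannon index over pathway burdens normalized by the number of genes
in each pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import FUNCTIONAL_CATEGORIES, PathwayDB
from .stats import TestResult, bh_adjust, kruskal_wallis

__all__ = [
    "PathwayBurden",
    "assign_mutations_to_pathways",
    "pathway_burden_test",
    "gene_burden_test",
    "percent_reduction",
    "shannon_pathway_diversity",
    "diversity_table",
    "diversity_group_test",
]


@dataclass
class PathwayBurden:
    functional: pd.DataFrame  # patients x pathways
    nonfunctional: pd.DataFrame
    genes_per_pathway: pd.Series

    def __post_init__(self) -> None:
        if (self.functional.to_numpy() < 0).any() or (self.nonfunctional.to_numpy() < 0).any():
            raise ValueError("burden counts must be >= 0")


def _genes_hit(catalog: pd.DataFrame, gene_intervals: pd.DataFrame, pad: int = 1000):
    """For each catalog row, the list of genes within ``pad`` bp."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in gene_intervals.itertuples(index=False):
        t = trees.setdefault(str(row.chrom), IntervalTree())
        t.addi(row.start - pad, row.end + pad, row.gene)
    hits = []
    for chrom, pos in zip(catalog["chrom"].astype(str), catalog["pos"]):
        t = trees.get(chrom)
        if t is None:
            hits.append([])
        else:
            hits.append(sorted(iv.data for iv in t.at(int(pos) - 1)))
    return hits


def assign_mutations_to_pathways(
    catalog: pd.DataFrame,
    pathways: PathwayDB,
    gene_intervals: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
) -> PathwayBurden:
    """Patients x pathways functional / non-functional mutation counts.

    A mutation links to gene g iff its position falls within
    [gene_start - 1000, gene_end + 1000), and to every pathway
    containing g. Without ``gene_intervals``, the catalog's own
    ``genes`` column (gene symbols within 1 kb, as emitted by the
    generator or an upstream annotator) is used. Pathway genes with no
    interval are skipped with a warning.
    """
    patients = (
        meta["patient_id"].astype(str).tolist()
        if meta is not None
        else sorted(catalog["patient_id"].astype(str).unique())
    )
    names = pathways.names

    if gene_intervals is not None:
        have = set(gene_intervals["gene"])
        missing = pathways.all_genes() - have
        if missing:
            warnings.warn(
                f"{len(missing)} pathway gene(s) lack intervals and are skipped",
                stacklevel=2,
            )
        hit_lists = _genes_hit(catalog, gene_intervals)
        genes_series = pd.Series(
            [",".join(h) for h in hit_lists], index=catalog.index
        )
    else:
        genes_series = catalog["genes"].fillna("").astype(str)

    gene_to_pw = pd.DataFrame(
        [(g, n) for n in names for g in pathways[n]], columns=["gene", "pathway"]
    )
    df = pd.DataFrame(
        {
            "mut": catalog.index,
            "patient_id": catalog["patient_id"].astype(str),
            "functional": catalog["category"].isin(FUNCTIONAL_CATEGORIES),
            "gene": genes_series.str.split(","),
        }
    ).explode("gene")
    df = df[df["gene"].astype(bool)]
    linked = df.merge(gene_to_pw, on="gene")
    # one increment per (mutation, pathway) even with multi-gene hits
    linked = linked.drop_duplicates(["mut", "pathway"])
    counts = (
        linked.groupby(["patient_id", "pathway", "functional"], observed=True)
        .size()
        .unstack("pathway", fill_value=0)
    )

    def pivot(functional: bool) -> pd.DataFrame:
        if functional in counts.index.get_level_values("functional"):
            sub = counts.xs(functional, level="functional")
        else:
            sub = pd.DataFrame(index=pd.Index([], name="patient_id"))
        return sub.reindex(index=patients, columns=names, fill_value=0).fillna(0).astype(int)

    return PathwayBurden(
        functional=pivot(True),
        nonfunctional=pivot(False),
        genes_per_pathway=pd.Series({n: pathways.gene_count(n) for n in names}),
    )


def pathway_burden_test(
    burden: PathwayBurden,
    meta: pd.DataFrame,
    which: str = "functional",
    fdr: float = 0.2,
) -> pd.DataFrame:
    """Per-pathway Kruskal-Wallis of per-patient counts, users vs non-users.

    BH-adjusted across pathways at the given FDR; group means, SEMs and
    the percent reduction in users are reported alongside.
    """
    counts = burden.functional if which == "functional" else burden.nonfunctional
    meta_idx = meta.set_index("patient_id")
    users = [p for p in counts.index if meta_idx.loc[p, "nsaid_user"]]
    nonusers = [p for p in counts.index if not meta_idx.loc[p, "nsaid_user"]]
    if len(users) < 2 or len(nonusers) < 2:
        raise ValueError("need >= 2 patients per group")
    rows = []
    for pw in counts.columns:
        cu = counts.loc[users, pw].to_numpy()
        cn = counts.loc[nonusers, pw].to_numpy()
        if cu.sum() == 0 and cn.sum() == 0:
            res = TestResult(statistic=0.0, p_value=1.0, n_used=len(cu) + len(cn))
        else:
            res = kruskal_wallis(cu, cn)
        rows.append(
            {
                "pathway": pw,
                "n_genes": int(burden.genes_per_pathway[pw]),
                "mean_user": float(cu.mean()),
                "sem_user": float(cu.std(ddof=1) / np.sqrt(len(cu))),
                "mean_nonuser": float(cn.mean()),
                "sem_nonuser": float(cn.std(ddof=1) / np.sqrt(len(cn))),
                "percent_reduction": percent_reduction(cu.mean(), cn.mean()),
                "H": res.statistic,
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["q"], out["significant"] = bh_adjust(out["p"].to_numpy(), fdr=fdr)
    return out


def gene_burden_test(
    catalog: pd.DataFrame,
    meta: pd.DataFrame,
    min_carriers: int = 5,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-gene functional-burden comparison with a carrier threshold.

    A gene is tested only if at least ``min_carriers`` users OR
    ``min_carriers`` non-users carry >= 1 functional mutation in it.
    """
    func = catalog[catalog["category"].isin(FUNCTIONAL_CATEGORIES)].copy()
    func = func[func["genes"].astype(str).str.len() > 0]
    rows = []
    meta_idx = meta.set_index("patient_id")
    users = meta_idx.index[meta_idx["nsaid_user"]]
    nonusers = meta_idx.index[~meta_idx["nsaid_user"]]
    # explode multi-gene links
    exploded = func.assign(gene=func["genes"].str.split(",")).explode("gene")
    per = exploded.groupby(["gene", "patient_id"]).size()
    for gene, sub in per.groupby(level="gene"):
        carriers = sub.index.get_level_values("patient_id")
        u_car = sum(p in set(carriers) for p in users)
        n_car = sum(p in set(carriers) for p in nonusers)
        if u_car < min_carriers and n_car < min_carriers:
            continue
        cu = sub.droplevel("gene").reindex(users, fill_value=0).to_numpy()
        cn = sub.droplevel("gene").reindex(nonusers, fill_value=0).to_numpy()
        res = kruskal_wallis(cu, cn)
        rows.append(
            {
                "gene": gene,
                "carriers_user": u_car,
                "carriers_nonuser": n_car,
                "mean_user": float(cu.mean()),
                "mean_nonuser": float(cn.mean()),
                "H": res.statistic,
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows, columns=[
        "gene", "carriers_user", "carriers_nonuser",
        "mean_user", "mean_nonuser", "H", "p",
    ])
    if len(out):
        out["q"], out["significant"] = bh_adjust(out["p"].to_numpy(), fdr=fdr)
    else:
        out["q"], out["significant"] = [], []
    return out


def percent_reduction(user_mean: float, nonuser_mean: float) -> float:
    """100 x (1 - user/nonuser); NaN when the non-user mean is zero."""
    if nonuser_mean == 0:
        return float("nan")
    return float(100.0 * (1.0 - user_mean / nonuser_mean))


def shannon_pathway_diversity(
    burden_row, genes_per_pathway, pathway_subset=None
) -> float:
    """Gene-count-normalized Shannon index of one patient's pathway burdens.

    m_i = count_i / genes_i over the subset, p_i = m_i / sum m_j,
    SI = -sum p_i ln p_i (0 ln 0 := 0); zero when all counts are zero
    (most concentrated). Scale-invariant in the counts.
    """
    counts = pd.Series(burden_row)
    genes = pd.Series(genes_per_pathway)
    if pathway_subset is not None:
        pathway_subset = list(pathway_subset)
        if not pathway_subset:
            raise ValueError("pathway subset must be non-empty")
        counts = counts[pathway_subset]
        genes = genes[pathway_subset]
    m = counts.to_numpy(dtype=float) / genes.to_numpy(dtype=float)
    total = m.sum()
    if total == 0:
        return 0.0
    p = m / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def diversity_table(
    burden: PathwayBurden, pathway_subset=None, which: str = "functional"
) -> pd.Series:
    counts = burden.functional if which == "functional" else burden.nonfunctional
    return pd.Series(
        {
            pid: shannon_pathway_diversity(
                counts.loc[pid], burden.genes_per_pathway, pathway_subset
            )
            for pid in counts.index
        },
        name="SI",
    )


def diversity_group_test(si: pd.Series, meta: pd.DataFrame) -> TestResult:
    """Kruskal-Wallis on per-patient Shannon indices, users vs non-users."""
    meta_idx = meta.set_index("patient_id")
    users = si[[p for p in si.index if meta_idx.loc[p, "nsaid_user"]]]
    nonusers = si[[p for p in si.index if not meta_idx.loc[p, "nsaid_user"]]]
    res = kruskal_wallis(users.to_numpy(), nonusers.to_numpy())
    res.detail.update(
        {"median_user": float(users.median()), "median_nonuser": float(nonusers.median())}
    )
    return res
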