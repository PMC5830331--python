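"""Statistical procedures used across the pipeline.

Every test returns a :class:`TestResult` so downstream tables share one
layout. The group comparison on arm densities is a patient-level
permutation test: the patient is the exchangeable unit, which preserves
the within-patient correlation across arms exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "sign_test",
    "kruskal_wallis",
    "fisher_exact_2x2",
    "bh_adjust",
    "group_effect_on_arm_density",
    "multivariable_lm",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_used: int
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


def sign_test(differences) -> TestResult:
    """Exact two-sided sign test; zero differences (ties) are excluded."""
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one difference")
    n_pos = int((d > 0).sum())
    n_neg = int((d < 0).sum())
    n_ties = int((d == 0).sum())
    n_used = n_pos + n_neg
    detail = {"n_positive": n_pos, "n_negative": n_neg, "n_ties": n_ties}
    if n_used == 0:
        warnings.warn("sign test: all differences are ties", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, n_used=0, detail=detail)
    p = sps.binomtest(n_pos, n_used, 0.5, alternative="two-sided").pvalue
    return TestResult(statistic=float(n_pos), p_value=float(min(p, 1.0)),
                      n_used=n_used, detail=detail)


def kruskal_wallis(group_a, group_b) -> TestResult:
    """Two-group Kruskal-Wallis (tie-corrected H, chi-square df=1 p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
        return TestResult(statistic=0.0, p_value=1.0, n_used=a.size + b.size,
                          detail={"n_a": int(a.size), "n_b": int(b.size)})
    h, p = sps.kruskal(a, b)
    return TestResult(statistic=float(h), p_value=float(p), n_used=a.size + b.size,
                      detail={"n_a": int(a.size), "n_b": int(b.size)})


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test (sum of hypergeometric probabilities
    no larger than the observed table's)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TestResult(statistic=np.nan, p_value=1.0, n_used=int(t.sum()),
                          detail={"table": t.tolist()})
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p), n_used=int(t.sum()),
                      detail={"table": t.tolist()})


def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up. Returns (q_values, rejected at fdr)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    rejected, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, rejected


def group_effect_on_arm_density(
    density_table: pd.DataFrame,
    meta: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Permutation test for a group effect on per-arm mutation density.

    Statistic: difference (users minus non-users) of group means of each
    patient's mean arm density. Patient labels are permuted, so the
    patient is the random-effect unit.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value", stacklevel=2)
    per_patient = density_table.groupby("patient_id")["density"].mean()
    meta_idx = meta.set_index("patient_id")
    y = per_patient.reindex(meta_idx.index).to_numpy()
    g = meta_idx["nsaid_user"].to_numpy(dtype=bool)
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("need >= 2 patients per group")
    obs = y[g].mean() - y[~g].mean()
    rng = np.random.default_rng(seed)
    n = len(y)
    k = int(g.sum())
    # vectorized label permutations: first k of each random order are "users"
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    sum_u = y[order].sum(axis=1)
    total = y.sum()
    perm_stats = sum_u / k - (total - sum_u) / (n - k)
    p = (1 + np.sum(np.abs(perm_stats) >= abs(obs) - 1e-12)) / (n_perm + 1)
    return TestResult(statistic=float(obs), p_value=float(p), n_used=n,
                      detail={"n_perm": n_perm, "n_users": k})


def multivariable_lm(
    response, covariates: pd.DataFrame, log1p: bool = True
) -> pd.DataFrame:
    """OLS of log(count+1) (default) on the given covariate columns.

    Returns a coefficient table (term, estimate, se, t, p). A rank-
    deficient design raises ``ValueError`` naming the aliased columns.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    if log1p:
        y = np.log1p(y)
    X = covariates.astype(float).copy()
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        aliased = []
        cols = list(Xd.columns)
        for j in range(1, len(cols)):
            sub = Xd.iloc[:, [c for c in range(len(cols)) if c != j]]
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                aliased.append(cols[j])
        raise ValueError(f"collinear design; aliased column(s): {aliased}")
    fit = sm.OLS(y, Xd).fit()
    return pd.DataFrame(
        {
            "term": Xd.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )


def results_to_frame(results: dict[str, TestResult]) -> pd.DataFrame:
    """Flatten named TestResults into the standard TSV layout."""
    import json

    rows = []
    for name, r in results.items():
        rows.append(
            {
                "test": name,
                "statistic": r.statistic,
                "p": r.p_value,
                "n": r.n_used,
                "detail": json.dumps(r.detail),
            }
        )
    return pd.DataFrame(rows)
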