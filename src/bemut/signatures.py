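"""Mutational-signature extraction and refitting.

Two complementary routes, mirroring common practice:

* de novo extraction: non-negative matrix factorization (generalized
  Kullback-Leibler objective, multiplicative updates) on bootstrap-
  perturbed spectra, with solutions clustered across resamples and rank
  selected by cluster stability (silhouette on cosine distance);
* refitting: per-sample forward selection of reference signatures by
  non-negative least squares on the normalized spectrum, discarding
  weights below a floor (0.06 by convention), with samples under the
  50-SNV minimum assigned zero counts from all signatures.

Per-signature mutation loads are compared between covariate groups by
ordinary least squares on log(count + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_samples

from .spectrum import SpectrumMatrix
from .stats import multivariable_lm

__all__ = [
    "SignatureModel",
    "RefitResult",
    "extract_signatures_nmf",
    "refit_weights",
    "cosine_similarity",
    "signature_load_regression",
]


def cosine_similarity(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class SignatureModel:
    """96 x k signature matrix with per-patient exposures."""

    W: np.ndarray  # 96 x k, column-stochastic
    H: np.ndarray  # k x patients, exposures in mutation counts
    k: int
    stability: np.ndarray  # per-signature, in [-1, 1]
    reconstruction_error: float
    patients: list[str] = field(default_factory=list)
    k_scan: dict = field(default_factory=dict)  # k -> (mean, min) stability

    def __post_init__(self) -> None:
        if not np.allclose(self.W.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("W columns must sum to 1")
        if (self.H < 0).any():
            raise ValueError("H must be non-negative")

    def exposures_frame(self) -> pd.DataFrame:
        cols = [f"E{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.H.T, index=self.patients, columns=cols)


def _kl_nmf(V: np.ndarray, k: int, rng: np.random.Generator, n_restarts: int):
    """Best-of-restarts KL-NMF of V (96 x patients)."""
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    best = None
    for _ in range(n_restarts):
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="kullback-leibler",
            max_iter=600,
            tol=1e-5,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(V)
        if best is None or model.reconstruction_err_ < best[2]:
            best = (W, model.components_, model.reconstruction_err_)
    return best


def _match_to_centroids(sigs: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Assign each of k signature vectors to a distinct centroid."""
    from scipy.optimize import linear_sum_assignment

    k = centroids.shape[1]
    cost = np.zeros((sigs.shape[1], k))
    for i in range(sigs.shape[1]):
        for j in range(k):
            cost[i, j] = 1 - cosine_similarity(sigs[:, i], centroids[:, j])
    row, col = linear_sum_assignment(cost)
    return col[np.argsort(row)]


def extract_signatures_nmf(
    spectrum: SpectrumMatrix,
    k_range=range(1, 4),
    n_resamples: int = 20,
    seed: int = 0,
    n_restarts: int = 3,
    min_stability: float = 0.8,
) -> SignatureModel:
    """Stability-selected de novo signature extraction.

    For each candidate k, NMF is run on ``n_resamples`` multinomial
    bootstrap perturbations of each patient's spectrum; the k x
    n_resamples solutions are matched across resamples and each
    cluster's silhouette (cosine distance) measures its stability. The
    selected k maximizes mean stability among ranks whose least stable
    signature clears ``min_stability`` (falling back to the overall
    best). Exposures are then refit on the unperturbed spectra by NNLS.
    """
    V = spectrum.counts.T.astype(float)  # 96 x P
    n_patients = V.shape[1]
    if n_patients < 2:
        raise ValueError("need >= 2 patients")
    if V.sum() < 96:
        raise ValueError("need >= 96 SNVs in total")
    k_range = list(k_range)
    if max(k_range) > min(96, n_patients):
        raise ValueError("k_range exceeds min(96, n_patients)")

    rng = np.random.default_rng(seed)
    totals = V.sum(axis=0).astype(int)
    probs = V / np.maximum(totals, 1)

    results = {}
    for k in k_range:
        W0, _, _ = _kl_nmf(V, k, rng, n_restarts)
        centroids = W0 / np.maximum(W0.sum(axis=0, keepdims=True), 1e-12)
        all_sigs, labels = [], []
        for _ in range(n_resamples):
            Vb = np.column_stack(
                [rng.multinomial(totals[p], probs[:, p]) for p in range(n_patients)]
            ).astype(float)
            Wb, _, _ = _kl_nmf(Vb, k, rng, n_restarts)
            Wb = Wb / np.maximum(Wb.sum(axis=0, keepdims=True), 1e-12)
            assign = _match_to_centroids(Wb, centroids)
            for i in range(k):
                all_sigs.append(Wb[:, i])
                labels.append(assign[i])
        S = np.array(all_sigs)
        labels = np.array(labels)
        cent = np.zeros((96, k))
        for j in range(k):
            cent[:, j] = S[labels == j].mean(axis=0)
        cent /= cent.sum(axis=0, keepdims=True)
        if k == 1:
            sims = np.array([cosine_similarity(s, cent[:, 0]) for s in S])
            stab = np.array([float(sims.mean())])
        else:
            sil = silhouette_samples(S, labels, metric="cosine")
            stab = np.array([float(sil[labels == j].mean()) for j in range(k)])
        results[k] = (cent, stab)

    # k = 1 reproduces trivially (every bootstrap solution is near the data
    # mean), so silhouettes are compared among k >= 2 and rank 1 is the
    # fallback when no multi-signature solution is stable.
    qualifying = [
        k for k in k_range if k >= 2 and results[k][1].min() >= min_stability
    ]
    if qualifying:
        k_sel = max(qualifying, key=lambda k: (results[k][1].mean(), -k))
    elif 1 in k_range:
        k_sel = 1
    else:
        k_sel = max(k_range, key=lambda k: (results[k][1].mean(), -k))
    W, stab = results[k_sel]

    # order signatures by total fitted exposure, largest first
    H = np.zeros((k_sel, n_patients))
    for p in range(n_patients):
        h, _ = nnls(W, V[:, p])
        H[:, p] = h
    order = np.argsort(-H.sum(axis=1))
    W, H, stab = W[:, order], H[order], stab[order]

    resid = np.linalg.norm(V - W @ H) / max(np.linalg.norm(V), 1e-12)
    return SignatureModel(
        W=W,
        H=H,
        k=k_sel,
        stability=stab,
        reconstruction_error=float(resid),
        patients=list(spectrum.patients),
        k_scan={k: (float(v[1].mean()), float(v[1].min())) for k, v in results.items()},
    )


@dataclass
class RefitResult:
    weights: pd.Series  # over all reference signatures, >= 0, sum <= 1
    assigned_counts: pd.Series
    residual: float
    below_min_flag: bool
    n_snv: int


def refit_weights(
    patient_spectrum,
    reference: pd.DataFrame,
    min_snv: int = 50,
    weight_floor: float = 0.06,
    tol: float = 1e-4,
) -> RefitResult:
    """Forward-selection NNLS refit of one sample against reference signatures.

    Signatures are added greedily while the squared error of the
    normalized spectrum drops by more than ``tol``; weights below
    ``weight_floor`` are discarded and the remainder refit. Samples with
    fewer than ``min_snv`` SNVs get zero assigned counts and the
    ``below_min_flag``.
    """
    x = np.asarray(patient_spectrum, dtype=float)
    if x.shape != (96,):
        raise ValueError("patient spectrum must be a 96-vector")
    R = reference.to_numpy()
    if not np.allclose(R.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("reference columns must each sum to 1")
    names = list(reference.columns)
    total = int(round(x.sum()))
    zero = pd.Series(0.0, index=names)
    if total < min_snv:
        return RefitResult(
            weights=zero.copy(),
            assigned_counts=zero.copy(),
            residual=float("nan"),
            below_min_flag=True,
            n_snv=total,
        )
    t = x / x.sum()

    def fit(cols: list[int]):
        w, r = nnls(R[:, cols], t)
        return w, r**2  # nnls returns the residual norm

    selected: list[int] = []
    sse = float(t @ t)
    remaining = list(range(len(names)))
    while remaining:
        best = None
        for c in remaining:
            _, s = fit(selected + [c])
            if best is None or s < best[1]:
                best = (c, s)
        if best is None or sse - best[1] <= tol:
            break
        selected.append(best[0])
        remaining.remove(best[0])
        sse = best[1]

    # apply the weight floor, refitting until stable
    while selected:
        w, sse = fit(selected)
        keep = w >= weight_floor
        if keep.all():
            break
        selected = [c for c, k in zip(selected, keep) if k]
    weights = zero.copy()
    if selected:
        w, sse = fit(selected)
        if w.sum() > 1.0:
            w = w / w.sum()
        for c, wi in zip(selected, w):
            weights.iloc[c] = wi
    residual = float(np.linalg.norm(t - R @ weights.to_numpy()))
    return RefitResult(
        weights=weights,
        assigned_counts=weights * total,
        residual=residual,
        below_min_flag=False,
        n_snv=total,
    )


def refit_cohort(
    spectrum: SpectrumMatrix, reference: pd.DataFrame, min_snv: int = 50, **kw
) -> pd.DataFrame:
    """Per-patient assigned mutation counts (patients x reference signatures)."""
    rows = {}
    for i, pid in enumerate(spectrum.patients):
        rows[pid] = refit_weights(
            spectrum.counts[i], reference, min_snv=min_snv, **kw
        ).assigned_counts
    return pd.DataFrame(rows).T.loc[spectrum.patients]


def top_signatures(assigned_counts: pd.DataFrame, min_share: float = 0.05) -> pd.Series:
    """Cohort-wide share per signature, restricted to those >= ``min_share``."""
    share = assigned_counts.sum(axis=0) / max(assigned_counts.to_numpy().sum(), 1e-12)
    return share[share >= min_share].sort_values(ascending=False)


def signature_load_regression(
    assigned_counts: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: list[str],
) -> dict[str, pd.DataFrame]:
    """Per-signature OLS of log(count + 1) on covariate columns.

    ``covariates`` may name any boolean meta column plus the composite
    ``"nsaid_never_smoker"`` (NSAID users who never smoked vs everyone
    else). Constant covariates raise ``ValueError``.
    """
    meta_idx = meta.set_index("patient_id").loc[assigned_counts.index]
    X = pd.DataFrame(index=assigned_counts.index)
    for cov in covariates:
        if cov == "nsaid_never_smoker":
            X[cov] = (meta_idx["nsaid_user"] & ~meta_idx["ever_smoker"]).astype(float)
        elif cov in meta_idx.columns:
            X[cov] = meta_idx[cov].astype(float)
        else:
            raise KeyError(f"unknown covariate {cov!r}")
        if X[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    out = {}
    for sig in assigned_counts.columns:
        out[sig] = multivariable_lm(assigned_counts[sig].to_numpy(), X, log1p=True)
    return out
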