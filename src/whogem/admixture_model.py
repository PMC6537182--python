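"""Admixture-proportion estimation and population statistics.

The model is the classic binomial admixture likelihood: sample i's dosage
at locus j is Binomial(2, p_ij) with p_ij = sum_k q_ik f_kj, where q_i is
the sample's simplex-constrained ancestry vector and f_k the ancestral
allele-frequency profile of component k.  Fitting uses plain multiplicative
EM updates (monotone in the log-likelihood) rather than quasi-Newton block
relaxation; the contract is likelihood monotonicity and parameter recovery,
not bitwise concordance with any external admixture program — externally
produced .Q files are accepted everywhere downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .containers import GenotypeMatrix, QMatrix

__all__ = [
    "CvErrorCurve",
    "estimate_q_supervised",
    "estimate_admixture_unsupervised",
    "admixture_cv_error",
    "fst_pairwise",
    "fis_per_population",
    "match_components",
]

_FREQ_EPS = 1e-6


@dataclass
class CvErrorCurve:
    """Masked-entry cross-validation error of the admixture model per K."""

    K_values: list[int]
    mean_errors: np.ndarray          # one value per K
    fold_errors: np.ndarray          # n_K x n_folds

    def argmin_K(self) -> int:
        return self.K_values[int(np.argmin(self.mean_errors))]


def _loglik(G: np.ndarray, obs: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    P = np.clip(Q @ F, _FREQ_EPS, 1 - _FREQ_EPS)
    ll = np.where(obs, G * np.log(P) + (2 - G) * np.log1p(-P), 0.0)
    return float(ll.sum())


def _em_iterate(
    G: np.ndarray,
    obs: np.ndarray,
    Q: np.ndarray,
    F: np.ndarray,
    update_F: bool,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative EM on the binomial admixture likelihood.

    ``obs`` marks entries that enter the likelihood (non-missing and, in
    cross-validation, unmasked).  Hidden entries are simply skipped.
    """
    Gz = np.where(obs, G, 0.0)
    G2 = np.where(obs, 2.0 - G, 0.0)
    n_obs = obs.sum(axis=1).astype(float)
    if (n_obs == 0).any():
        raise ValueError("sample with no observed genotypes")
    trace = [_loglik(G, obs, Q, F)]
    for _ in range(max_iter):
        P = np.clip(Q @ F, _FREQ_EPS, 1 - _FREQ_EPS)
        A = Gz / P
        B = G2 / (1.0 - P)
        Q_new = Q * (A @ F.T + B @ (1.0 - F).T) / (2.0 * n_obs[:, None])
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        if update_F:
            Ca = F * (Q.T @ A)
            Cb = (1.0 - F) * (Q.T @ B)
            denom = Ca + Cb
            F_new = np.where(denom > 0, Ca / np.where(denom > 0, denom, 1.0), F)
            F = np.clip(F_new, _FREQ_EPS, 1 - _FREQ_EPS)
        Q = Q_new
        trace.append(_loglik(G, obs, Q, F))
        if trace[-1] - trace[-2] < tol:
            break
    return Q, F, trace


def estimate_q_supervised(
    G: GenotypeMatrix,
    labels: pd.Series | dict,
    max_iter: int = 2000,
    tol: float = 1e-7,
) -> tuple[QMatrix, np.ndarray]:
    """Supervised admixture: ancestral frequencies from labeled samples.

    F is estimated as per-class observed allele frequencies (with a 0.5
    pseudo-count per class-locus); every sample's q then maximizes the
    binomial likelihood over the simplex by EM with F held fixed.
    Component order follows the sorted class labels.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labels = labels.dropna()
    classes = sorted(map(str, labels.unique()))
    if not classes:
        raise ValueError("no labeled samples")
    idx = {s: i for i, s in enumerate(G.sample_ids)}
    unknown = [s for s in labels.index if s not in idx]
    if unknown:
        raise KeyError(f"labeled samples absent from genotypes: {unknown[:5]}")

    D = G.dosage
    obs = ~np.isnan(D)
    if (~obs).all(axis=1).any():
        raise ValueError("sample with all genotypes missing")
    K = len(classes)
    M = G.n_variants
    F = np.empty((K, M))
    for k, cls in enumerate(classes):
        rows = [idx[s] for s in labels.index[labels.astype(str) == cls]]
        sub = D[rows]
        sub_obs = ~np.isnan(sub)
        alt = np.nansum(sub, axis=0)
        n = sub_obs.sum(axis=0)
        F[k] = (alt + 0.5) / (2.0 * n + 1.0)
    F = np.clip(F, _FREQ_EPS, 1 - _FREQ_EPS)

    Q0 = np.full((G.n_samples, K), 1.0 / K)
    Gz = np.nan_to_num(D)
    Q, F, trace = _em_iterate(Gz, obs, Q0, F, update_F=False, max_iter=max_iter, tol=tol)
    _assert_monotone(trace)
    return QMatrix(list(G.sample_ids), Q, classes), F


def estimate_admixture_unsupervised(
    G: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-7,
    obs_mask: np.ndarray | None = None,
) -> tuple[QMatrix, np.ndarray, list[float]]:
    """Unsupervised admixture by alternating EM on Q and F.

    Initialization: k-means on the top-10 PCA scores of the mean-imputed
    dosages, perturbed by seeded noise.  The returned components are
    canonicalized by descending total weight.  The log-likelihood trace
    (monotone non-decreasing) is returned for auditing.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > G.n_samples:
        raise ValueError("K exceeds the number of samples")
    D = G.dosage
    obs = ~np.isnan(D) if obs_mask is None else (obs_mask & ~np.isnan(D))
    Gz = np.nan_to_num(D)

    if K == 1:
        alt = (Gz * obs).sum(axis=0)
        n = obs.sum(axis=0)
        F = np.clip((alt / np.maximum(2.0 * n, 1.0))[None, :], _FREQ_EPS, 1 - _FREQ_EPS)
        Q = np.ones((G.n_samples, 1))
        return QMatrix(list(G.sample_ids), Q), F, [_loglik(Gz, obs, Q, F)]

    rng = np.random.default_rng(seed)
    X = G.imputed()
    X = X - X.mean(axis=0)
    n_pc = min(10, min(X.shape) - 1) or 1
    # deterministic truncated SVD for the initialization scores
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_pc] * S[:n_pc]
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K, n_init=5, random_state=int(rng.integers(2**31)))
    hard = km.fit_predict(scores)
    Q = np.full((G.n_samples, K), 0.1 / max(K - 1, 1))
    Q[np.arange(G.n_samples), hard] = 0.9
    Q = Q * rng.uniform(0.9, 1.1, size=Q.shape)
    Q /= Q.sum(axis=1, keepdims=True)
    F = np.empty((K, G.n_variants))
    for k in range(K):
        members = hard == k
        if members.any():
            alt = (Gz[members] * obs[members]).sum(axis=0)
            n = obs[members].sum(axis=0)
            F[k] = (alt + 0.5) / (2.0 * n + 1.0)
        else:
            F[k] = rng.uniform(0.2, 0.8, size=G.n_variants)
    F = np.clip(F, _FREQ_EPS, 1 - _FREQ_EPS)

    Q, F, trace = _em_iterate(Gz, obs, Q, F, update_F=True, max_iter=max_iter, tol=tol)
    _assert_monotone(trace)
    if not np.isfinite(trace[-1]):
        raise RuntimeError("non-finite likelihood in admixture EM")
    order = np.argsort(-Q.sum(axis=0), kind="stable")
    return QMatrix(list(G.sample_ids), Q[:, order]), F[order], trace


def _assert_monotone(trace: list[float], slack: float = 1e-6) -> None:
    diffs = np.diff(trace)
    if (diffs < -slack * np.maximum(1.0, np.abs(trace[:-1]))).any():
        raise RuntimeError("EM log-likelihood decreased; numerical failure")


def admixture_cv_error(
    G: GenotypeMatrix,
    K_range,
    n_folds: int = 5,
    mask_fraction: float = 0.1,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> CvErrorCurve:
    """Masked-entry cross-validation of the admixture model.

    Per fold, a seeded random mask hides ``mask_fraction`` of the
    non-missing entries; the model is fit on the rest, and the error is
    the RMSE of the predicted dosage 2 * sum_k q_ik f_kj over the hidden
    entries.  The curve reports the mean over folds for each K.
    """
    K_values = sorted(int(k) for k in K_range)
    if not K_values:
        raise ValueError("K_range is empty")
    if not 0 < mask_fraction < 1:
        raise ValueError("mask_fraction must lie in (0, 1)")
    observed = ~np.isnan(G.dosage)
    rng = np.random.default_rng(seed)
    Gz = np.nan_to_num(G.dosage)

    masks = []
    for _ in range(n_folds):
        for _attempt in range(20):
            mask = observed & (rng.random(G.dosage.shape) < mask_fraction)
            train = observed & ~mask
            if mask.any() and (train.sum(axis=1) > 0).all() and (train.sum(axis=0) > 0).all():
                break
        else:
            raise RuntimeError("could not draw a mask leaving every sample and locus observed")
        masks.append(mask)

    fold_errors = np.empty((len(K_values), n_folds))
    for ki, K in enumerate(K_values):
        for fi, mask in enumerate(masks):
            train_obs = observed & ~mask
            Q, F, _ = estimate_admixture_unsupervised(
                G, K, seed=int(rng.integers(2**31)), max_iter=max_iter, tol=tol,
                obs_mask=train_obs,
            )
            pred = 2.0 * (Q.theta @ F)
            err = (Gz - pred)[mask]
            fold_errors[ki, fi] = float(np.sqrt(np.mean(err**2)))
    return CvErrorCurve(K_values, fold_errors.mean(axis=1), fold_errors)


def fst_pairwise(F: np.ndarray) -> np.ndarray:
    """Pairwise Fst between components from ancestral allele frequencies.

    Nei's ratio of averages: Fst = (mean_j H_T - mean_j H_S) / mean_j H_T
    with H_S the mean within-component heterozygosity and H_T the
    heterozygosity at the mean frequency of the pair.
    """
    F = np.asarray(F, dtype=float)
    K = F.shape[0]
    if K < 2:
        raise ValueError("need at least two components")
    out = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            fa, fb = F[a], F[b]
            hs = (2 * fa * (1 - fa) + 2 * fb * (1 - fb)) / 2.0
            fbar = (fa + fb) / 2.0
            ht = 2 * fbar * (1 - fbar)
            mean_ht = ht.mean()
            if mean_ht == 0:
                warnings.warn(f"Fst undefined for components {a},{b}: all loci monomorphic")
                out[a, b] = out[b, a] = np.nan
            else:
                out[a, b] = out[b, a] = (mean_ht - hs.mean()) / mean_ht
    return out


def fis_per_population(G: GenotypeMatrix, labels: pd.Series | dict) -> pd.Series:
    """Inbreeding coefficient Fis = 1 - mean(Ho)/mean(He) per population.

    Ho is the observed heterozygote fraction (dosage 1) and He = 2p(1-p)
    the expected one; means are taken over the loci polymorphic within
    the population.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    idx = {s: i for i, s in enumerate(G.sample_ids)}
    result = {}
    for pop in sorted(map(str, labels.dropna().unique())):
        rows = [idx[s] for s in labels.index[labels.astype(str) == pop] if s in idx]
        if len(rows) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 samples")
        sub = G.dosage[rows]
        obs = ~np.isnan(sub)
        n = obs.sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nansum(sub, axis=0) / (2.0 * n)
        poly = (n > 0) & (p > 0) & (p < 1)
        if not poly.any():
            warnings.warn(f"population {pop!r} has no polymorphic loci; Fis undefined")
            result[pop] = np.nan
            continue
        ho = np.nansum(sub[:, poly] == 1, axis=0) / n[poly]
        he = 2 * p[poly] * (1 - p[poly])
        result[pop] = float(1.0 - ho.mean() / he.mean())
    return pd.Series(result, name="Fis")


def match_components(Q_est: QMatrix, Q_ref: QMatrix) -> np.ndarray:
    """Permutation of Q_est's columns best aligning it with Q_ref.

    Hungarian assignment on the negative column correlations; resolves
    the label-switching ambiguity of unsupervised fits.
    """
    if Q_est.K != Q_ref.K:
        raise ValueError("component counts differ")
    A = Q_est.reorder(Q_ref.sample_ids).theta
    B = Q_ref.theta
    C = np.zeros((Q_est.K, Q_est.K))
    for i in range(Q_est.K):
        for j in range(Q_est.K):
            sa, sb = A[:, i].std(), B[:, j].std()
            C[i, j] = 0.0 if sa == 0 or sb == 0 else np.corrcoef(A[:, i], B[:, j])[0, 1]
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(Q_est.K, dtype=int)
    perm[cols] = rows
    return perm
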