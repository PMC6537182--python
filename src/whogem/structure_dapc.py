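"""PCA / k-means / discriminant-analysis arm of K determination.

Complements the admixture cross-validation curve: dosages are reduced by
PCA, k-means is scanned over K and scored with a BIC, and discriminant
analysis of the retained principal components (DAPC) yields group
assignments.  A separate helper clusters samples into populations from
their admixture proportions (Euclidean distance, average linkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .containers import GenotypeMatrix, QMatrix

__all__ = ["PcaScores", "BicCurve", "pca_scores", "bic_scan", "dapc_fit", "cluster_by_admixture"]


@dataclass
class PcaScores:
    sample_ids: list[str]
    scores: np.ndarray                 # N x P
    explained_variance_ratio: np.ndarray


@dataclass
class BicCurve:
    K_values: list[int]
    bic: np.ndarray
    assignments: dict[int, np.ndarray]
    seed: int

    def argmin_K(self) -> int:
        return self.K_values[int(np.argmin(self.bic))]


def pca_scores(G: GenotypeMatrix, n_components: int = 80) -> PcaScores:
    """Principal-component scores of the mean-imputed, centered dosages.

    Deterministic up to sign; the sign of each axis is fixed so that its
    largest-magnitude loading is positive.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = G.imputed()
    X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncating")
        n_components = max(rank, 1)
    # sign convention from loadings
    flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    scores = U[:, :n_components] * S[:n_components]
    var = S**2
    evr = var[:n_components] / var.sum() if var.sum() > 0 else np.zeros(n_components)
    return PcaScores(list(G.sample_ids), scores, evr)


def bic_scan(scores: PcaScores, K_range, n_starts: int = 10, seed: int = 0) -> BicCurve:
    """k-means over a range of K, scored with BIC(K) = N ln(WSS/N) + K ln(N)."""
    X = scores.scores
    N = X.shape[0]
    K_values = sorted(int(k) for k in K_range)
    if max(K_values) > N:
        raise ValueError("K exceeds the number of samples")
    if max(K_values) >= N:
        warnings.warn("K = N gives WSS = 0; capping K_range at N - 1")
        K_values = [k for k in K_values if k <= N - 1]
    rng = np.random.default_rng(seed)
    # canonicalize the row order fed to k-means so the scan is exactly
    # invariant to permutations of the input samples
    order = np.lexsort(X.T[::-1])
    inverse = np.empty(N, dtype=int)
    inverse[order] = np.arange(N)
    Xs = X[order]
    bic = np.empty(len(K_values))
    assignments: dict[int, np.ndarray] = {}
    for i, K in enumerate(K_values):
        km = KMeans(n_clusters=K, n_init=n_starts, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(Xs)[inverse]
        wss = float(km.inertia_)
        bic[i] = N * np.log(max(wss, 1e-300) / N) + K * np.log(N)
        assignments[K] = labels
    return BicCurve(K_values, bic, assignments, seed)


@dataclass
class DapcResult:
    axes: np.ndarray                   # P x (n_groups - 1) discriminant loadings
    sample_scores: np.ndarray          # N x (n_groups - 1)
    posterior: np.ndarray              # N x n_groups
    groups: list[str]
    assigned: np.ndarray               # N predicted group labels


def dapc_fit(scores: PcaScores, groups) -> DapcResult:
    """Linear discriminant axes on retained PCs with posterior memberships.

    Classic pooled-covariance LDA: at most n_groups - 1 axes maximizing
    the between/within variance ratio; posteriors from the Gaussian
    discriminant model.  The PC count is truncated to N - n_groups when
    necessary to keep the within-group covariance well conditioned.
    """
    y = np.asarray([str(g) for g in groups])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least two groups")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("every group needs at least two members")
    X = scores.scores
    max_p = X.shape[0] - len(classes)
    if X.shape[1] > max_p:
        warnings.warn(f"truncating PCs from {X.shape[1]} to {max_p}")
        X = X[:, :max_p]
    lda = LinearDiscriminantAnalysis(solver="svd", store_covariance=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(X, y)
        sample_scores = lda.transform(X)
        posterior = lda.predict_proba(X)
        assigned = lda.predict(X)
    return DapcResult(lda.scalings_[:, : sample_scores.shape[1]], sample_scores,
                      posterior, list(lda.classes_), assigned)


def cluster_by_admixture(Q: QMatrix, K_groups: int) -> np.ndarray:
    """Assign samples to populations by UPGMA on their admixture rows.

    Agglomerative clustering with Euclidean metric and average linkage,
    cut at ``K_groups`` clusters; labels are renamed by descending
    cluster size ('G1' largest).  SciPy's linkage breaks merge-height
    ties by the lowest pair index, which keeps the result deterministic.
    """
    if K_groups < 1 or K_groups > Q.n_samples:
        raise ValueError("K_groups must lie in [1, N]")
    if K_groups == 1:
        return np.array(["G1"] * Q.n_samples)
    Z = linkage(Q.theta, method="average", metric="euclidean")
    raw = fcluster(Z, t=K_groups, criterion="maxclust")
    sizes = {c: (raw == c).sum() for c in np.unique(raw)}
    order = sorted(sizes, key=lambda c: (-sizes[c], c))
    rename = {c: f"G{i + 1}" for i, c in enumerate(order)}
    return np.array([rename[c] for c in raw])
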