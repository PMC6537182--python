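"""Genomic-prediction baselines behind one fit/predict contract.

Five standard whole-genome regression methods: RR-BLUP (ridge on marker
effects, variance ratio by maximum likelihood), G-BLUP (BLUP on a
VanRaden kinship; mathematically equivalent to RR-BLUP), BayesB (Gibbs
sampler with per-marker inclusion and a scaled-t effect prior), RKHS
(Gaussian-kernel ridge, bandwidth by the median heuristic, penalty by
GCV) and LASSO (coordinate descent with the penalty chosen by internal
cross-validation and the 1-SE rule).  All methods consume the same
mean-imputed, column-centered marker matrix so comparisons are fair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import GenotypeMatrix

__all__ = ["GenomicModel", "fit_genomic_model", "predict_genomic", "METHODS"]

METHODS = ("rrblup", "gblup", "bayesb", "rkhs", "lasso")


@dataclass
class GenomicModel:
    method: str
    intercept: float
    marker_ids: list[str]
    col_means: np.ndarray                     # training imputation/centering means
    effects: np.ndarray | None = None         # rrblup / bayesb / lasso
    train_W: np.ndarray | None = None         # gblup / rkhs
    train_alpha: np.ndarray | None = None     # kernel/kinship sample weights
    hyper: dict = field(default_factory=dict)
    seed: int = 0
    train_sample_ids: list[str] = field(default_factory=list)


def _centered_markers(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    X = G.imputed()
    mu = X.mean(axis=0)
    return X - mu, mu


def _ml_kernel_blup(K: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, float]:
    """ML estimation of the variance ratio for y = 1*mu + g, g ~ N(0, s_g^2 K).

    Profiles the likelihood over delta = s_e^2 / s_g^2 on the spectrum of
    K; returns (mu, alpha, delta) with alpha = (K + delta I)^-1 (y - mu).
    """
    n = len(y)
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)
    # search the ratio on a scale-free axis (relative to the mean
    # eigenvalue) so rescaling the kernel leaves the fit unchanged
    scale = max(w.mean(), 1e-300)

    def neg_ll(log_delta: float) -> float:
        d = np.exp(log_delta) * scale
        v = w + d
        mu = (ones_t * yt / v).sum() / (ones_t**2 / v).sum()
        r = yt - mu * ones_t
        s2 = (r**2 / v).sum() / n
        return 0.5 * (n * np.log(max(s2, 1e-300)) + np.log(v).sum())

    res = minimize_scalar(neg_ll, bounds=(-14.0, 14.0), method="bounded",
                          options={"xatol": 1e-11})
    delta = float(np.exp(res.x) * scale)
    v = w + delta
    mu = float((ones_t * yt / v).sum() / (ones_t**2 / v).sum())
    alpha = U @ ((yt - mu * ones_t) / v)
    return mu, alpha, delta


def fit_genomic_model(
    G_train: GenotypeMatrix,
    y_train: pd.DataFrame | np.ndarray,
    method: str,
    hyper: dict | None = None,
    seed: int = 0,
) -> GenomicModel:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    hyper = dict(hyper or {})
    if isinstance(y_train, pd.DataFrame):
        trait = [c for c in y_train.columns if c != "sample_id"][0]
        y_map = dict(zip(y_train["sample_id"], y_train[trait]))
        y = np.array([y_map[s] for s in G_train.sample_ids], dtype=float)
    else:
        y = np.asarray(y_train, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 training samples")
    if y.std() == 0:
        raise ValueError("zero-variance phenotype")

    X = G_train.imputed()
    mu_cols = X.mean(axis=0)
    W = X - mu_cols
    model = GenomicModel(method=method, intercept=0.0, marker_ids=list(G_train.variant_ids),
                         col_means=mu_cols, hyper=hyper, seed=seed,
                         train_sample_ids=list(G_train.sample_ids))

    if method == "rrblup":
        mu, alpha, delta = _ml_kernel_blup(W @ W.T, y)
        model.intercept = mu
        model.effects = W.T @ alpha
        model.hyper["delta"] = delta
    elif method == "gblup":
        p_hat = mu_cols / 2.0
        c = float((2 * p_hat * (1 - p_hat)).sum())
        if c <= 0:
            raise ValueError("monomorphic marker set; kinship undefined")
        Kmat = (W @ W.T) / c
        mu, alpha, delta = _ml_kernel_blup(Kmat, y)
        model.intercept = mu
        model.train_W = W
        model.train_alpha = alpha
        model.hyper.update({"delta": delta, "vanraden_c": c})
    elif method == "bayesb":
        model = _fit_bayesb(model, W, y, hyper, seed)
    elif method == "rkhs":
        d2 = _sq_dists(W, W)
        h = float(hyper.get("h", np.median(d2[np.triu_indices_from(d2, k=1)])))
        h = max(h, 1e-8)
        Kmat = np.exp(-d2 / h)
        lam = _gcv_lambda(Kmat, y)
        n = len(y)
        A = np.linalg.solve(Kmat + lam * np.eye(n), np.eye(n))
        mu = float(y.mean())
        model.intercept = mu
        model.train_W = W
        model.train_alpha = A @ (y - mu)
        model.hyper.update({"h": h, "lambda": lam})
    elif method == "lasso":
        model = _fit_lasso(model, W, y, hyper, seed)
    return model


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    sa = (A**2).sum(axis=1)
    sb = (B**2).sum(axis=1)
    return np.clip(sa[:, None] + sb[None, :] - 2 * A @ B.T, 0.0, None)


def _gcv_lambda(K: np.ndarray, y: np.ndarray) -> float:
    """Generalized cross-validation over a log-spaced ridge-penalty grid."""
    n = len(y)
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    yc = y - y.mean()
    yt = U.T @ yc
    best_lam, best_score = 1.0, np.inf
    for lam in np.logspace(-4, 4, 33):
        shrink = w / (w + lam)
        resid2 = ((1 - shrink) * yt) ** 2
        denom = (n - shrink.sum()) ** 2
        score = n * resid2.sum() / max(denom, 1e-12)
        if score < best_score:
            best_lam, best_score = float(lam), score
    return best_lam


def _fit_bayesb(model: GenomicModel, W: np.ndarray, y: np.ndarray,
                hyper: dict, seed: int) -> GenomicModel:
    """Gibbs sampler for BayesB: marker effects with point-mass exclusion.

    Prior: each marker excluded with probability pi (default 0.95);
    included effects ~ N(0, s_j^2), s_j^2 ~ scaled-inv-chi2(nu, S).
    Posterior-mean effects over the kept samples are returned.
    """
    rng = np.random.default_rng(seed)
    n, m = W.shape
    n_iter = int(hyper.get("n_iter", 5000))
    burn_in = int(hyper.get("burn_in", min(1000, n_iter // 5)))
    pi = float(hyper.get("pi", 0.95))
    nu = float(hyper.get("nu", 4.1))
    var_y = y.var()
    # prior scale so the expected total genetic variance matches var_y / 2
    mean_x2 = (W**2).mean() * n
    S = float(hyper.get("S", var_y * (nu - 2) / nu * 0.5 / max((1 - pi) * mean_x2 / n, 1e-8)))

    x2 = (W**2).sum(axis=0)
    beta = np.zeros(m)
    sigma_j2 = np.full(m, S * nu / (nu - 2))
    mu = float(y.mean())
    e = y - mu
    sigma_e2 = float(e.var()) or 1.0
    beta_sum = np.zeros(m)
    mu_sum = 0.0
    kept = 0
    log_odds_prior = np.log((1 - pi) / pi)

    for it in range(n_iter):
        # intercept
        mu_new = rng.normal(mu + e.mean(), np.sqrt(sigma_e2 / n))
        e += mu - mu_new
        mu = mu_new
        for j in range(m):
            if x2[j] == 0:
                continue
            e_j = e + W[:, j] * beta[j]         # residual excluding marker j
            rhs = W[:, j] @ e_j
            # integrate the effect out to get the inclusion odds
            c = x2[j] / sigma_e2 + 1.0 / sigma_j2[j]
            log_bf = 0.5 * (rhs / sigma_e2) ** 2 / c - 0.5 * np.log(sigma_j2[j] * c)
            p_in = 1.0 / (1.0 + np.exp(-(log_odds_prior + log_bf)))
            if rng.random() < p_in:
                post_var = 1.0 / c
                beta[j] = rng.normal(rhs / sigma_e2 * post_var, np.sqrt(post_var))
                sigma_j2[j] = (S * nu + beta[j] ** 2) / rng.chisquare(nu + 1)
            else:
                beta[j] = 0.0
                sigma_j2[j] = S * nu / rng.chisquare(nu)
            e = e_j - W[:, j] * beta[j]
        sigma_e2 = float((e @ e + 1e-6) / rng.chisquare(n + 2))
        if it >= burn_in:
            beta_sum += beta
            mu_sum += mu
            kept += 1
    model.intercept = mu_sum / kept
    model.effects = beta_sum / kept
    model.hyper.update({"n_iter": n_iter, "burn_in": burn_in, "pi": pi, "nu": nu, "S": S})
    return model


def _fit_lasso(model: GenomicModel, W: np.ndarray, y: np.ndarray,
               hyper: dict, seed: int) -> GenomicModel:
    from sklearn.linear_model import Lasso, LassoCV
    from sklearn.model_selection import KFold

    cv = KFold(n_splits=int(hyper.get("cv", 5)), shuffle=True, random_state=seed % (2**31))
    lcv = LassoCV(cv=cv, alphas=int(hyper.get("n_alphas", 50)), max_iter=5000)
    lcv.fit(W, y)
    # 1-SE rule: strongest penalty whose CV error is within one standard
    # error of the minimum
    mse = lcv.mse_path_.mean(axis=1)
    se = lcv.mse_path_.std(axis=1) / np.sqrt(lcv.mse_path_.shape[1])
    i_min = int(np.argmin(mse))
    ok = mse <= mse[i_min] + se[i_min]
    alpha_1se = float(lcv.alphas_[ok].max())
    final = Lasso(alpha=alpha_1se, max_iter=5000)
    final.fit(W, y)
    model.intercept = float(final.intercept_)
    model.effects = final.coef_
    model.hyper.update({"alpha": alpha_1se, "alpha_min": float(lcv.alpha_)})
    return model


def predict_genomic(model: GenomicModel, G_new: GenotypeMatrix) -> pd.DataFrame:
    """Predict phenotypes for new samples from a fitted genomic model."""
    if list(G_new.variant_ids) != model.marker_ids:
        extra = set(G_new.variant_ids) - set(model.marker_ids)
        missing = set(model.marker_ids) - set(G_new.variant_ids)
        if extra or missing:
            raise ValueError(
                f"marker sets differ; only in new data: {sorted(extra)[:5]}, "
                f"only in model: {sorted(missing)[:5]}"
            )
        order = [G_new.variant_ids.index(v) for v in model.marker_ids]
        G_new = G_new.subset_variants(np.array(order))
    X = G_new.dosage.copy()
    idx = np.where(np.isnan(X))
    X[idx] = model.col_means[idx[1]]       # impute with *training* means
    W = X - model.col_means
    if model.effects is not None:
        yhat = model.intercept + W @ model.effects
    elif model.method == "gblup":
        c = model.hyper["vanraden_c"]
        Kx = (W @ model.train_W.T) / c
        yhat = model.intercept + Kx @ model.train_alpha
    elif model.method == "rkhs":
        Kx = np.exp(-_sq_dists(W, model.train_W) / model.hyper["h"])
        yhat = model.intercept + Kx @ model.train_alpha
    else:
        raise ValueError(f"cannot predict with method {model.method!r}")
    return pd.DataFrame({"sample_id": G_new.sample_ids, "prediction": yhat})
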