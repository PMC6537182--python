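"""Admixture-environment association and variation partitioning.

Two analyses: a Pearson correlation screen between every admixture
component and every environmental variable with Bonferroni control, and
redundancy-analysis (RDA) variation partitioning of the admixture matrix
into fractions explained by climate only, geography only, their shared
(collinear) part, and a residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QMatrix

__all__ = ["RdaPartition", "component_env_correlations", "rda_partition"]


@dataclass
class RdaPartition:
    fraction_climate_only: float
    fraction_shared: float
    fraction_geography_only: float
    residual: float
    total_constrained_r2: float
    permutation_p: float
    adjusted: dict | None = None


def component_env_correlations(
    Q: QMatrix, env: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Pearson r for every (component, variable) pair with Bonferroni control.

    The family is every tested pair (K x n_vars); a pair is flagged
    significant when its two-sided p falls below alpha / family size.
    """
    merged = Q.to_frame().merge(env, on="sample_id")
    if len(merged) < 3:
        raise ValueError("need at least 3 joined samples")
    variables = [c for c in env.columns if c != "sample_id"]
    family = Q.K * len(variables)
    rows = []
    for comp in Q.component_names:
        x = merged[comp].to_numpy(float)
        for var in variables:
            y = merged[var].to_numpy(float)
            if np.std(y) == 0 or np.std(x) == 0:
                warnings.warn(f"zero variance for pair ({comp}, {var}); correlation undefined")
                rows.append({"component": comp, "variable": var, "r": np.nan,
                             "p": np.nan, "significant": False})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"component": comp, "variable": var, "r": float(r),
                         "p": float(p), "significant": bool(p < alpha / family)})
    out = pd.DataFrame(rows)
    out.attrs["family_size"] = family
    out.attrs["alpha"] = alpha
    return out


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0)


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-10) == len(keep) + 1:
            keep.append(j)
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping collinear predictor columns: {dropped}")
    return X[:, keep], [names[j] for j in keep]


def _explained_ss(Y: np.ndarray, X: np.ndarray) -> float:
    """Sum of squares of the fitted values from regressing Y on centered X."""
    if X.shape[1] == 0:
        return 0.0
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Yhat = X @ B
    return float((Yhat**2).sum())


def _residualize(A: np.ndarray, Z: np.ndarray) -> np.ndarray:
    if Z.shape[1] == 0:
        return A
    B, *_ = np.linalg.lstsq(Z, A, rcond=None)
    return A - Z @ B


def rda_partition(
    Q: QMatrix,
    climate: pd.DataFrame,
    geography: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> RdaPartition:
    """Partition admixture variation between climate and geography.

    RDA(Y | X) is multivariate least squares of the centered admixture
    matrix on centered predictors; the explained fraction is
    trace(Yhat' Yhat) / trace(Y' Y).  Partial fractions residualize both
    Y and the focal predictors on the conditioning set first
    (Frisch-Waugh), so the identity a + b + c + residual = 1 holds
    exactly with b = full - a - c.  Raw (unadjusted) fractions are
    reported as the primary output to keep the identity exact; adjusted
    R-squared values are attached as a secondary field.

    Significance of the full model comes from unrestricted permutation
    of the rows of Y.
    """
    merged = Q.to_frame().merge(climate, on="sample_id").merge(
        geography, on="sample_id", suffixes=("_clim", "_geo")
    )
    n = len(merged)
    clim_cols = [c for c in climate.columns if c != "sample_id"]
    geo_cols = [c for c in geography.columns if c != "sample_id"]
    clim_cols = [c if c in merged.columns else f"{c}_clim" for c in clim_cols]
    geo_cols = [c if c in merged.columns else f"{c}_geo" for c in geo_cols]
    if len(clim_cols) + len(geo_cols) >= n:
        raise ValueError("more predictors than samples")
    Y = _center(merged[Q.component_names].to_numpy(float))
    Xc = _center(merged[clim_cols].to_numpy(float))
    Xg = _center(merged[geo_cols].to_numpy(float))
    Xc, clim_kept = _drop_collinear(Xc, clim_cols)
    Xg, geo_kept = _drop_collinear(Xg, geo_cols)
    Xall, _ = _drop_collinear(np.column_stack([Xc, Xg]), clim_kept + geo_kept)
    if Xall.shape[1] >= n:
        raise ValueError("more predictors than samples")

    tot = float((Y**2).sum())
    if tot == 0:
        raise ValueError("admixture matrix has zero variance")
    full = _explained_ss(Y, Xall) / tot
    # unique fractions via Frisch-Waugh residualization
    a = _explained_ss(_residualize(Y, Xg), _residualize(Xc, Xg)) / tot
    c = _explained_ss(_residualize(Y, Xc), _residualize(Xg, Xc)) / tot
    b = full - a - c
    residual = 1.0 - full

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        Yp = Y[rng.permutation(n)]
        if _explained_ss(Yp, Xall) / float((Yp**2).sum()) >= full:
            count += 1
    p = (1 + count) / (n_perm + 1)

    def _adj(frac: float, p_terms: int) -> float:
        if n - p_terms - 1 <= 0:
            return np.nan
        return 1.0 - (1.0 - frac) * (n - 1) / (n - p_terms - 1)

    adjusted = {
        "full": _adj(full, Xall.shape[1]),
        "climate_total": _adj(_explained_ss(Y, Xc) / tot, Xc.shape[1]),
        "geography_total": _adj(_explained_ss(Y, Xg) / tot, Xg.shape[1]),
    }
    return RdaPartition(a, b, c, residual, full, p, adjusted)
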