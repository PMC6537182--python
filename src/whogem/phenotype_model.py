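"""Trait modelling from admixture proportions.

Two stages: least-squares means extract one adjusted value per accession
from augmented block designs (y = mu + block + accession + error), and a
best-minimum-model search regresses the trait on subsets of the
admixture components.  Because the K proportions sum to one the full
model is collinear, so the search space is every non-empty proper subset
of components (exhaustive at K = 8), ranked by BIC and then backward
pruned at a 5% significance benchmark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import QMatrix

__all__ = ["LinearFit", "ls_means", "fit_admixture_lm", "predict_trait"]


@dataclass
class LinearFit:
    """A fitted admixture-component regression."""

    components: list[str]        # selected non-intercept terms
    coefficients: pd.Series      # 'Intercept' first, then the components
    std_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    r2: float
    model_p: float
    n_used: int
    trait: str = "trait"
    search_trace: list = field(default_factory=list)


def ls_means(raw: pd.DataFrame, response: str = "score") -> pd.DataFrame:
    """Accession LS means from a two-way fixed-effects block design.

    Fits y = mu + block_i + accession_j by OLS (treatment contrasts) and
    reports, for each accession, its predicted value averaged over every
    block with equal weight.  In a balanced design this reduces to the
    arithmetic accession mean.
    """
    for col in ("accession", "block", response):
        if col not in raw.columns:
            raise ValueError(f"raw score table missing column {col!r}")
    raw = raw.dropna(subset=[response])
    accs = sorted(raw["accession"].astype(str).unique())
    blocks = sorted(raw["block"].astype(str).unique())
    if len(accs) < 2:
        raise ValueError("need at least two accessions")
    _check_connected(raw)

    acc_d = pd.get_dummies(raw["accession"].astype(str), dtype=float)[accs].iloc[:, 1:]
    blk_d = pd.get_dummies(raw["block"].astype(str), dtype=float)[blocks].iloc[:, 1:]
    X = np.column_stack([np.ones(len(raw)), blk_d.to_numpy(), acc_d.to_numpy()])
    beta, *_ = np.linalg.lstsq(X, raw[response].to_numpy(float), rcond=None)
    mu = beta[0]
    blk_eff = np.concatenate([[0.0], beta[1 : len(blocks)]])
    acc_eff = np.concatenate([[0.0], beta[len(blocks) :]])
    mean_blk = blk_eff.mean()
    values = mu + mean_blk + acc_eff
    return pd.DataFrame({"sample_id": accs, response: values})


def _check_connected(raw: pd.DataFrame) -> None:
    """Blocks and accessions must form one connected bipartite design."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for _, rec in raw.iterrows():
        a, b = find(f"a:{rec['accession']}"), find(f"b:{rec['block']}")
        if a != b:
            parent[a] = b
    roots = {find(f"a:{a}") for a in raw["accession"].astype(str).unique()}
    if len(roots) > 1:
        comps: dict[str, list[str]] = {}
        for a in raw["accession"].astype(str).unique():
            comps.setdefault(find(f"a:{a}"), []).append(a)
        raise ValueError(f"disconnected design; components: {sorted(comps.values())}")


def _ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, X).fit()


def fit_admixture_lm(
    traits: pd.DataFrame,
    Q: QMatrix,
    alpha: float = 0.05,
    search: str = "exhaustive",
    trait: str | None = None,
) -> LinearFit:
    """Best-minimum linear model of a trait on admixture components.

    Exhaustive mode scores every non-empty proper subset of the K
    components by BIC (ties broken by fewer terms, then lexicographic
    order), then backward-prunes terms until every retained predictor has
    p <= alpha.  Stepwise mode grows/shrinks greedily by BIC instead of
    enumerating, with the same pruning rule.
    """
    if trait is None:
        trait = [c for c in traits.columns if c != "sample_id"][0]
    merged = traits[["sample_id", trait]].dropna().merge(Q.to_frame(), on="sample_id")
    n = len(merged)
    K = Q.K
    if K < 2:
        raise ValueError("need at least two admixture components")
    if n < K + 2:
        raise ValueError(f"need at least K + 2 = {K + 2} samples with trait and Q; have {n}")
    y = merged[trait].to_numpy(float)
    comps = list(Q.component_names)
    Xall = merged[comps].to_numpy(float)

    def design(subset: tuple[str, ...]) -> np.ndarray:
        cols = [comps.index(c) for c in subset]
        return np.column_stack([np.ones(n), Xall[:, cols]])

    trace: list[tuple[tuple[str, ...], float]] = []
    if y.std() == 0:
        warnings.warn("trait is constant; returning intercept-only model")
        return _finalize((), y, design, alpha, n, trait, trace)

    if search == "exhaustive":
        candidates = [
            tuple(sorted(c))
            for r in range(1, K)
            for c in combinations(comps, r)
        ]
        best, best_key = None, None
        for sub in candidates:
            res = _ols(y, design(sub))
            # BIC compared at fixed precision so exactly aliased subsets
            # (the simplex constraint makes every (K-1)-subset equivalent)
            # tie and fall through to the size/lexicographic rule
            key = (np.round(res.bic, 6), len(sub), sub)
            trace.append((sub, float(res.bic)))
            if best_key is None or key < best_key:
                best, best_key = sub, key
    elif search == "stepwise":
        best = ()
        best_bic = _ols(y, design(best)).bic
        improved = True
        while improved:
            improved = False
            moves = [best + (c,) for c in comps if c not in best and len(best) + 1 < K]
            moves += [tuple(t for t in best if t != c) for c in best]
            for sub in moves:
                res = _ols(y, design(tuple(sub)))
                trace.append((tuple(sub), float(res.bic)))
                if res.bic < best_bic - 1e-10:
                    best, best_bic, improved = tuple(sub), res.bic, True
    else:
        raise ValueError("search must be 'exhaustive' or 'stepwise'")

    # backward pruning at the significance benchmark
    current = tuple(best)
    while current:
        res = _ols(y, design(current))
        pvals = res.pvalues[1:]
        if (pvals <= alpha).all():
            break
        current = tuple(c for i, c in enumerate(current) if i != int(np.argmax(pvals)))
    if not current:
        warnings.warn("no subset with all terms significant; returning intercept-only model")
    return _finalize(current, y, design, alpha, n, trait, trace)


def _finalize(subset, y, design, alpha, n, trait, trace) -> LinearFit:
    res = _ols(y, design(subset))
    names = ["Intercept"] + list(subset)
    return LinearFit(
        components=list(subset),
        coefficients=pd.Series(res.params, index=names),
        std_errors=pd.Series(res.bse, index=names),
        t_values=pd.Series(res.tvalues, index=names),
        p_values=pd.Series(res.pvalues, index=names),
        r2=float(res.rsquared) if subset else 0.0,
        model_p=float(res.f_pvalue) if subset else np.nan,
        n_used=n,
        trait=trait,
        search_trace=trace,
    )


def predict_trait(fit: LinearFit, Q: QMatrix) -> pd.DataFrame:
    """Predicted trait values: intercept + sum of selected component effects."""
    missing = [c for c in fit.components if c not in Q.component_names]
    if missing:
        raise KeyError(f"Q matrix lacks components {missing}")
    yhat = np.full(Q.n_samples, fit.coefficients["Intercept"])
    for c in fit.components:
        yhat = yhat + fit.coefficients[c] * Q.theta[:, Q.component_names.index(c)]
    return pd.DataFrame({"sample_id": Q.sample_ids, fit.trait: yhat})
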