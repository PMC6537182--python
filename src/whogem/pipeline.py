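"""Multi-criteria determination of the number of admixture components.

Composes three independent lines of evidence: (1) the masked-entry
cross-validation error of the admixture model over a K range, (2) a
k-means/BIC scan of PCA-reduced genotypes, and (3) geographic
leave-one-out validation, which breaks the near-ties the first two
steps leave by preferring the smallest K that geolocates samples as
well as the best.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import admixture_model, provenance, structure_dapc
from .containers import GenotypeMatrix

__all__ = ["KSelection", "determine_k"]


@dataclass
class KSelection:
    K_star: int
    cv_region: list[int]
    bic_region: list[int]
    loo_table: pd.DataFrame
    cv_curve: admixture_model.CvErrorCurve
    bic_curve: structure_dapc.BicCurve


def determine_k(
    G: GenotypeMatrix,
    geo: pd.DataFrame,
    K_range,
    seed: int = 0,
    n_folds: int = 3,
    n_pcs: int = 20,
    mantel_perms: int = 199,
    cutoff_quantile: float = 0.75,
    em_max_iter: int = 200,
    M: int = 10,
) -> KSelection:
    """Pick the most parsimonious K supported by CV error, BIC and geography.

    The CV region holds every K whose mean masked-entry error is within
    one standard error (across folds, at the argmin) of the minimum; the
    BIC region is the analogous one-standard-deviation band of the BIC
    curve.  Leave-one-out geolocation is then run for every K spanned by
    the union of the two regions, and the final K minimizes median error
    while maximizing country accuracy under the parsimony rule of
    :func:`whogem.provenance.select_k`.
    """
    K_values = sorted(int(k) for k in K_range)
    rng = np.random.default_rng(seed)

    curve = admixture_model.admixture_cv_error(
        G, K_values, n_folds=n_folds, seed=int(rng.integers(2**31)),
        max_iter=em_max_iter,
    )
    i_min = int(np.argmin(curve.mean_errors))
    se = curve.fold_errors[i_min].std(ddof=1) / np.sqrt(n_folds) if n_folds > 1 else 0.0
    cv_region = [k for k, e in zip(curve.K_values, curve.mean_errors)
                 if e <= curve.mean_errors[i_min] + se]

    scores = structure_dapc.pca_scores(G, n_components=min(n_pcs, G.n_samples - 1))
    bic = structure_dapc.bic_scan(scores, K_values, seed=int(rng.integers(2**31)))
    bic_band = bic.bic.std(ddof=1) / np.sqrt(len(bic.bic)) if len(bic.bic) > 1 else 0.0
    bic_region = [k for k, b in zip(bic.K_values, bic.bic) if b <= bic.bic.min() + bic_band]

    lo = min(min(cv_region), min(bic_region))
    hi = max(max(cv_region), max(bic_region))
    candidates = [k for k in K_values if lo <= k <= hi]
    if len(candidates) < 2:
        # widen to the two nearest neighbours so parsimony has a choice
        extra = sorted(K_values, key=lambda k: abs(k - candidates[0]))[:2]
        candidates = sorted(set(candidates) | set(extra))

    geoD = provenance.geographic_distance_matrix(geo)
    il = np.tril_indices(geoD.shape[0], k=-1)
    cutoff = float(np.quantile(geoD[il], cutoff_quantile))
    loo_by_K: dict[int, provenance.LooSummary] = {}
    for K in candidates:
        Q, _, _ = admixture_model.estimate_admixture_unsupervised(
            G, K, seed=int(rng.integers(2**31)), max_iter=em_max_iter, tol=1e-6,
        )
        Qr = Q.reorder(list(geo["sample_id"]))
        genD = provenance.admixture_distance_matrix(Qr)
        try:
            cal = provenance.calibrate(genD, geoD, cutoff, n_perm=mantel_perms,
                                       seed=int(rng.integers(2**31)))
        except ValueError:
            continue
        loo_by_K[K] = provenance.loo_cross_validate(geo, Q, cal, M=M)
    K_star, table = provenance.select_k(loo_by_K)
    return KSelection(K_star, cv_region, bic_region, table, curve, bic)
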