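"""Seeded landscape-genetics data generator.

Emulates the statistical structure the rest of the pipeline assumes:
K ancestral populations anchored at map centroids, admixture proportions
that decay with distance from each centroid (isolation by distance),
Balding-Nichols ancestral allele frequencies, traits that are linear in
the admixture vector, and spatially structured climate covariates.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` streams; repeated calls with the same
configuration are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, QMatrix

__all__ = [
    "LandscapeConfig",
    "SyntheticDataset",
    "make_landscape",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_environment",
    "make_dataset",
]


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Defaults sketch a Mediterranean-basin-like study: a handful of
    differentiated populations spread over tens of degrees, moderate
    differentiation (``fst_f`` = 0.15), admixture that decays over a few
    degrees of distance, and tight per-sample Dirichlet noise.
    """

    K: int = 4
    n_per_pop: int = 50
    lat_range: tuple[float, float] = (30.0, 45.0)
    lon_range: tuple[float, float] = (-10.0, 25.0)
    decay_rho: float = 3.0          # admixture distance-decay scale, degrees
    dirichlet_conc: float = 100.0   # per-sample admixture noise concentration
    fst_f: float = 0.15             # Balding-Nichols differentiation
    n_loci: int = 1000
    pop_spread: float = 1.0         # s.d. of sample scatter around centroid, degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_per_pop < 1:
            raise ValueError("n_per_pop must be >= 1")
        if not 0.0 < self.fst_f < 1.0:
            raise ValueError("fst_f must lie in (0, 1)")
        if self.decay_rho <= 0:
            raise ValueError("decay_rho must be positive")


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    q_true: QMatrix
    freqs_true: np.ndarray
    geo: pd.DataFrame
    traits: pd.DataFrame
    env: pd.DataFrame


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_landscape(config: LandscapeConfig) -> tuple[pd.DataFrame, QMatrix]:
    """Place K population centroids on the map and draw admixed samples.

    Each sample scatters (Gaussian, s.d. ``pop_spread``) around its
    population centroid.  Its true admixture vector is proportional to
    ``exp(-d(x, c_k) / decay_rho)`` over centroids, then perturbed with
    Dirichlet noise of concentration ``dirichlet_conc * q``.  The country
    label of a sample is the Voronoi cell (nearest centroid) it falls in,
    so "correct country" accuracy is well defined downstream.
    """
    rng_cent, rng_pos, rng_dir = _streams(config.seed, 3)
    lat0, lat1 = config.lat_range
    lon0, lon1 = config.lon_range
    diag = float(np.hypot(lat1 - lat0, lon1 - lon0))
    min_sep = 0.05 * diag if config.K > 1 else 0.0

    centroids = None
    for _ in range(100):
        cand = np.column_stack(
            [rng_cent.uniform(lat0, lat1, config.K), rng_cent.uniform(lon0, lon1, config.K)]
        )
        if config.K == 1:
            centroids = cand
            break
        d = np.linalg.norm(cand[:, None, :] - cand[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > min_sep:
            centroids = cand
            break
    if centroids is None:
        raise RuntimeError(
            "degenerate landscape: could not place centroids with minimum "
            f"separation {min_sep:.3f} degrees in 100 attempts"
        )

    n = config.K * config.n_per_pop
    pop_idx = np.repeat(np.arange(config.K), config.n_per_pop)
    pos = centroids[pop_idx] + rng_pos.normal(scale=config.pop_spread, size=(n, 2))
    pos[:, 0] = np.clip(pos[:, 0], lat0, lat1)
    pos[:, 1] = np.clip(pos[:, 1], lon0, lon1)

    # distance-decay mixture, shifted by the row minimum for stability in
    # the decay_rho -> 0 limit (nearest centroid then gets weight 1)
    dist = np.linalg.norm(pos[:, None, :] - centroids[None, :, :], axis=-1)
    logw = -(dist - dist.min(axis=1, keepdims=True)) / config.decay_rho
    q = np.exp(logw)
    q /= q.sum(axis=1, keepdims=True)

    if config.K > 1 and np.isfinite(config.dirichlet_conc):
        alpha = config.dirichlet_conc * q
        draws = rng_dir.standard_gamma(alpha)
        totals = draws.sum(axis=1, keepdims=True)
        # a row of all-zero gamma draws (possible for vanishing alphas)
        # falls back to the noiseless mixture
        ok = totals[:, 0] > 0
        noisy = np.divide(draws, totals, out=np.zeros_like(draws), where=totals > 0)
        q = np.where(ok[:, None], noisy, q)
    q /= q.sum(axis=1, keepdims=True)

    nearest = dist.argmin(axis=1)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    geo = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "latitude": pos[:, 0],
            "longitude": pos[:, 1],
            "country": [f"C{c + 1}" for c in nearest],
            "population": [f"P{p + 1}" for p in pop_idx],
        }
    )
    return geo, QMatrix(sample_ids, q)


def simulate_genotypes(
    q_true: QMatrix, n_loci: int, fst_f: float, seed: int
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw dosages under the Balding-Nichols model.

    A common frequency p_j ~ U(0.05, 0.95) per locus; each ancestral
    population's frequency f_kj ~ Beta(p(1-F)/F, (1-p)(1-F)/F); dosages
    g_ij ~ Binomial(2, sum_k q_ik f_kj).  Loci are independent (the
    pipeline consumes LD-pruned SNPs).
    """
    if not 0.0 < fst_f < 1.0:
        raise ValueError("fst_f must lie in (0, 1)")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    K = q_true.K
    p = rng.uniform(0.05, 0.95, size=n_loci)
    ratio = (1.0 - fst_f) / fst_f
    F = rng.beta(np.broadcast_to(p * ratio, (K, n_loci)), np.broadcast_to((1 - p) * ratio, (K, n_loci)))
    P = np.clip(q_true.theta @ F, 0.0, 1.0)
    G = rng.binomial(2, P).astype(float)
    gm = GenotypeMatrix(
        sample_ids=list(q_true.sample_ids),
        variant_ids=[f"snp{j}" for j in range(n_loci)],
        dosage=G,
        chrom=np.array(["1"] * n_loci),
        pos=np.arange(1, n_loci + 1),
    )
    return gm, F


def simulate_trait(
    q_true: QMatrix,
    beta: np.ndarray,
    sigma: float,
    seed: int,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Trait linear in the admixture vector: y = b0 + sum_k b_k q_k + noise."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != q_true.K + 1:
        raise ValueError("beta must have length K + 1 (intercept first)")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    y = beta[0] + q_true.theta @ beta[1:]
    if sigma > 0:
        y = y + rng.normal(scale=sigma, size=y.shape)
    return pd.DataFrame({"sample_id": q_true.sample_ids, trait_name: y})


def simulate_environment(
    geo: pd.DataFrame,
    n_vars: int = 19,
    seed: int = 0,
    noise_sd: float = 0.5,
    linear_only: bool = False,
    include_elevation: bool = True,
) -> pd.DataFrame:
    """Spatially structured climate-like covariates.

    Each variable is an affine function of (lat, lon) plus a smooth
    low-order polynomial term and Gaussian noise, with seeded
    coefficients.  The last variable is pure noise — a null control for
    correlation screens.  ``include_elevation`` adds a smooth 'elevation'
    column for geography-conditioned analyses.
    """
    if geo.empty:
        raise ValueError("geo table is empty")
    rng = np.random.default_rng(seed)
    lat = geo["latitude"].to_numpy(float)
    lon = geo["longitude"].to_numpy(float)
    zlat = (lat - lat.mean()) / (lat.std() or 1.0)
    zlon = (lon - lon.mean()) / (lon.std() or 1.0)
    out = {"sample_id": geo["sample_id"].to_numpy()}
    for v in range(n_vars):
        a, b = rng.normal(scale=2.0, size=2)
        x = a * zlat + b * zlon
        if not linear_only:
            c, d, e = rng.normal(scale=0.5, size=3)
            x = x + c * zlat**2 + d * zlon**2 + e * zlat * zlon
        if v == n_vars - 1:
            x = np.zeros_like(x)  # null control: noise only
        if noise_sd > 0:
            x = x + rng.normal(scale=noise_sd if v < n_vars - 1 else 1.0, size=x.shape)
        out[f"bio{v + 1}"] = x
    if include_elevation:
        a, b, c = rng.normal(scale=1.0, size=3)
        elev = 500 + 200 * (a * zlat + b * zlon + c * zlat * zlon)
        if noise_sd > 0:
            elev = elev + rng.normal(scale=50 * noise_sd, size=elev.shape)
        out["elevation"] = elev
    return pd.DataFrame(out)


def make_dataset(
    config: LandscapeConfig,
    beta: np.ndarray | None = None,
    sigma: float = 0.5,
    n_env: int = 19,
) -> SyntheticDataset:
    """Full dataset: landscape, genotypes, a Q-linear trait and environment."""
    geo, q_true = make_landscape(config)
    sub = np.random.SeedSequence(config.seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]
    genotypes, F = simulate_genotypes(q_true, config.n_loci, config.fst_f, seeds[0])
    if beta is None:
        rng_b = np.random.default_rng(seeds[1])
        beta = np.concatenate([[2.0], rng_b.normal(scale=2.0, size=config.K)])
    traits = simulate_trait(q_true, beta, sigma, seeds[2])
    env = simulate_environment(geo, n_vars=n_env, seed=seeds[3])
    counts = pd.Series(geo["sample_id"]).value_counts()
    if (counts != 1).any():
        warnings.warn("duplicate sample ids in generated dataset")
    return SyntheticDataset(genotypes, q_true, F, geo, traits, env)
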