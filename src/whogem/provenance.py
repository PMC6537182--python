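"""Geolocation of samples from admixture proportions.

The predictor places a sample by comparing its admixture vector with a
geo-referenced reference panel: the Euclidean admixture distance to every
panel unit is computed, the smallest distance is converted to a
geographic search radius through a calibrated linear genetic-to-
geographic relationship (an isolation-by-distance fit below a distance
cutoff), and the predicted point is a weighted displacement from the
best-matching unit's location, clipped to that radius.  Exact ties in
the smallest distance — common with highly selfing organisms whose
accessions can share an admixture vector — are pooled into a tie set
whose geographic centroid serves as the origin.

The same code path serves two panel granularities: accession-level
panels (each reference sample is a unit) for placing novel samples, and
population-level panels (units are population mean admixture vectors and
geographic centroids) for leave-one-out validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import QMatrix, validate_geo_table

__all__ = [
    "ReferencePanel",
    "CalibrationModel",
    "PlacementResult",
    "LooSummary",
    "PAPER_CALIBRATION",
    "admixture_distance_matrix",
    "geographic_distance_matrix",
    "mantel_test",
    "calibrate",
    "predict_location",
    "panel_from_accessions",
    "panel_from_populations",
    "loo_cross_validate",
    "select_k",
]

KM_PER_DEGREE = 2 * np.pi * 6371.0 / 360.0  # ~111.19 km at the equator


@dataclass
class ReferencePanel:
    """Geo-referenced reference units (accessions or population means)."""

    unit_ids: list[str]
    theta: np.ndarray            # n_units x K, rows on the simplex
    latitude: np.ndarray
    longitude: np.ndarray
    country: list[str]
    population: list[str]
    level: str = "accession"     # 'accession' | 'population'
    n_members: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        if len(self.unit_ids) < 2:
            raise ValueError("a reference panel needs at least two units")
        if np.abs(self.theta.sum(axis=1) - 1).max() > 1e-6:
            raise ValueError("panel admixture rows must sum to 1")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def K(self) -> int:
        return self.theta.shape[1]


@dataclass
class CalibrationModel:
    """Linear genetic-to-geographic calibration with its distance cutoff.

    ``intercept``/``slope`` map an admixture distance Gen to a geographic
    distance Geo = intercept + slope * Gen, valid below ``cutoff`` (all in
    the units of ``metric``).  Mantel statistics document the
    isolation-by-distance signal the fit rests on.
    """

    intercept: float
    slope: float
    cutoff: float
    mantel_r_all: float = np.nan
    mantel_r_filtered: float = np.nan
    mantel_p: float = np.nan
    adj_r2: float = np.nan
    metric: str = "euclidean-degrees"
    deg_to_km: float = 111.32

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.metric not in ("euclidean-degrees", "great-circle-km"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def radius(self, gen_distance: float) -> float:
        return self.intercept + self.slope * gen_distance


#: Calibration constants published for the Mediterranean *M. truncatula*
#: panel (K = 8 supervised admixture, 950-km isolation-by-distance
#: cutoff).  The geographic metric is tagged euclidean-degrees with a
#: 111.32 km/degree reporting factor; this unit reading is inferred, not
#: stated with the constants, and is flagged here for that reason.
PAPER_CALIBRATION = CalibrationModel(
    intercept=0.204,
    slope=4.973,
    cutoff=950.0 / 111.32,
    mantel_r_all=0.294,
    mantel_r_filtered=0.78,
    mantel_p=1e-4,
    adj_r2=0.61,
    metric="euclidean-degrees",
    deg_to_km=111.32,
)


@dataclass
class PlacementResult:
    sample_id: str
    latitude: float
    longitude: float
    delta_min: float
    tie_ids: list[str]
    used_ids: list[str]
    used_deltas: np.ndarray
    weights: np.ndarray
    radius: float
    confidence: str              # 'within-calibration-range' | 'extrapolated'


@dataclass
class LooSummary:
    per_sample: pd.DataFrame     # sample_id, population, error, correct_country
    median_error: float
    country_accuracy: float
    per_population_accuracy: pd.Series
    metric: str = "euclidean-degrees"


def admixture_distance_matrix(Q: QMatrix) -> np.ndarray:
    """Pairwise Euclidean distances between admixture rows (in [0, sqrt 2])."""
    X = Q.theta
    sq = (X**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    D = np.sqrt(np.clip(D2, 0.0, None))
    np.fill_diagonal(D, 0.0)
    return D


def geographic_distance_matrix(geo: pd.DataFrame, metric: str = "euclidean-degrees") -> np.ndarray:
    validate_geo_table(geo)
    lat = geo["latitude"].to_numpy(float)
    lon = geo["longitude"].to_numpy(float)
    if metric == "euclidean-degrees":
        P = np.column_stack([lat, lon])
        sq = (P**2).sum(axis=1)
        D = np.sqrt(np.clip(sq[:, None] + sq[None, :] - 2 * P @ P.T, 0.0, None))
    elif metric == "great-circle-km":
        D = _haversine_matrix(lat, lon)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return D


def _haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    la = np.radians(lat)
    lo = np.radians(lon)
    dla = la[:, None] - la[None, :]
    dlo = lo[:, None] - lo[None, :]
    a = np.sin(dla / 2) ** 2 + np.cos(la)[:, None] * np.cos(la)[None, :] * np.sin(dlo / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _haversine(lat1, lon1, lat2, lon2) -> float:
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * 6371.0 * np.arcsin(np.sqrt(min(max(a, 0.0), 1.0))))


def mantel_test(D1: np.ndarray, D2: np.ndarray, n_perm: int = 9999, seed: int = 0) -> tuple[float, float]:
    """One-sided Mantel test of positive association between two distance matrices.

    r is the Pearson correlation of the lower-triangle entries;
    significance comes from jointly permuting the rows and columns of D2:
    p = (1 + #{permuted r >= observed}) / (n_perm + 1).
    """
    D1 = np.asarray(D1, float)
    D2 = np.asarray(D2, float)
    if D1.shape != D2.shape or D1.shape[0] != D1.shape[1]:
        raise ValueError("distance matrices must be square and conformable")
    n = D1.shape[0]
    if n < 3:
        raise ValueError("need at least 3 objects")
    il = np.tril_indices(n, k=-1)
    x = D1[il]
    if x.std() == 0 or D2[il].std() == 0:
        raise ValueError("zero variance in a distance matrix; correlation undefined")
    xz = (x - x.mean()) / x.std()

    def _r(mat: np.ndarray) -> float:
        y = mat[il]
        return float((xz * (y - y.mean())).mean() / y.std())

    r_obs = _r(D2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _r(D2[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)


def calibrate(
    genD: np.ndarray,
    geoD: np.ndarray,
    cutoff: float,
    n_perm: int = 999,
    seed: int = 0,
    metric: str = "euclidean-degrees",
    deg_to_km: float = 111.32,
) -> CalibrationModel:
    """Fit the genetic-to-geographic line on pairs closer than ``cutoff``.

    Reports the Mantel statistic on the full matrices, the plain Pearson
    correlation of the retained (sub-cutoff) pairs, and the OLS fit
    Geo = a + b * Gen with its adjusted r-squared.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    r_all, p_all = mantel_test(genD, geoD, n_perm=n_perm, seed=seed)
    il = np.tril_indices(genD.shape[0], k=-1)
    gen, geo = genD[il], geoD[il]
    keep = geo < cutoff
    if keep.sum() < 3:
        raise ValueError(f"fewer than 3 pairs below the cutoff {cutoff}")
    x, y = gen[keep], geo[keep]
    if x.std() == 0:
        raise ValueError("no genetic-distance variance below the cutoff")
    b, a = np.polyfit(x, y, 1)
    yhat = a + b * x
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    n_pairs = keep.sum()
    r2 = 1 - ss_res / ss_tot
    adj = 1 - (1 - r2) * (n_pairs - 1) / (n_pairs - 2)
    r_filt = float(np.corrcoef(x, y)[0, 1])
    return CalibrationModel(
        intercept=float(a), slope=float(b), cutoff=float(cutoff),
        mantel_r_all=r_all, mantel_r_filtered=r_filt, mantel_p=p_all,
        adj_r2=float(adj), metric=metric, deg_to_km=deg_to_km,
    )


def _to_plane(lat: np.ndarray, lon: np.ndarray, lat0: float, lon0: float, metric: str):
    """Coordinates of panel points relative to an origin, in metric units."""
    if metric == "euclidean-degrees":
        return np.column_stack([lat - lat0, lon - lon0])
    # local tangent plane in km around the origin
    ky = KM_PER_DEGREE
    kx = KM_PER_DEGREE * np.cos(np.radians(lat0))
    return np.column_stack([(lat - lat0) * ky, (lon - lon0) * kx])


def _from_plane(vec: np.ndarray, lat0: float, lon0: float, metric: str) -> tuple[float, float]:
    if metric == "euclidean-degrees":
        return lat0 + float(vec[0]), lon0 + float(vec[1])
    ky = KM_PER_DEGREE
    kx = KM_PER_DEGREE * np.cos(np.radians(lat0))
    return lat0 + float(vec[0]) / ky, lon0 + float(vec[1]) / kx


def predict_location(
    q: np.ndarray,
    panel: ReferencePanel,
    cal: CalibrationModel,
    M: int = 10,
    tie_tol: float = 1e-9,
    sample_id: str = "query",
) -> PlacementResult:
    """Place one admixture vector on the map.

    Steps: admixture distances to every panel unit; the tie set of units
    within relative ``tie_tol`` of the smallest distance; origin at the
    tie set's geographic centroid; search radius from the calibration;
    weighted displacement toward the up-to-M nearest non-tie units with
    weights w_m = delta_min / delta_m, clipped so the predicted point
    stays within the radius of the origin.
    """
    q = np.asarray(q, float).ravel()
    if q.shape[0] != panel.K:
        raise ValueError(f"query has {q.shape[0]} components, panel has {panel.K}")
    if abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("query admixture vector must sum to 1")

    delta = np.sqrt(((panel.theta - q[None, :]) ** 2).sum(axis=1))
    delta_min = float(delta.min())
    tie = delta <= delta_min * (1.0 + tie_tol) + tie_tol  # absolute term covers delta_min = 0
    lat0 = float(panel.latitude[tie].mean())
    lon0 = float(panel.longitude[tie].mean())
    # a fitted line with a negative intercept can map a tiny genetic
    # distance to a negative geographic radius; clamp at zero (the
    # prediction then collapses onto the tie-set centroid)
    radius = max(0.0, cal.radius(delta_min))
    confidence = "extrapolated" if radius > cal.cutoff else "within-calibration-range"

    if delta_min <= tie_tol:
        # exact match: the tie-set centroid is the prediction
        tie_ids = [panel.unit_ids[i] for i in np.flatnonzero(tie)]
        return PlacementResult(sample_id, lat0, lon0, delta_min, tie_ids,
                               tie_ids, delta[tie], np.ones(int(tie.sum())),
                               radius, confidence)

    order = np.argsort(delta, kind="stable")
    m_eff = min(M, panel.n_units)
    cut = delta[order[m_eff - 1]]
    used = delta <= cut * (1.0 + tie_tol)  # boundary ties all retained
    weights = delta_min / delta[used]
    used_idx = np.flatnonzero(used)

    disp_idx = used_idx[~tie[used_idx]]
    if disp_idx.size:
        rel = _to_plane(panel.latitude[disp_idx], panel.longitude[disp_idx],
                        lat0, lon0, cal.metric)
        w = delta_min / delta[disp_idx]
        D = (w[:, None] * rel).sum(axis=0)
    else:
        D = np.zeros(2)
    norm = float(np.linalg.norm(D))
    vec = D if norm == 0 else min(1.0, radius / norm) * D
    lat_pred, lon_pred = _from_plane(vec, lat0, lon0, cal.metric)

    # invariant: never farther than the radius from the tie-set centroid
    if np.linalg.norm(vec) > radius + 1e-9:
        raise AssertionError("predicted point escaped the calibrated radius")

    return PlacementResult(
        sample_id, lat_pred, lon_pred, delta_min,
        [panel.unit_ids[i] for i in np.flatnonzero(tie)],
        [panel.unit_ids[i] for i in used_idx],
        delta[used_idx], weights, radius, confidence,
    )


def panel_from_accessions(Q: QMatrix, geo: pd.DataFrame) -> ReferencePanel:
    """Accession-level panel: every geo-referenced sample is a unit."""
    geo = validate_geo_table(geo).set_index("sample_id")
    ids = [s for s in Q.sample_ids if s in geo.index]
    Qr = Q.reorder(ids)
    sub = geo.loc[ids]
    return ReferencePanel(
        ids, Qr.theta, sub["latitude"].to_numpy(), sub["longitude"].to_numpy(),
        [str(c) for c in sub.get("country", pd.Series("?", index=sub.index))],
        [str(p) for p in sub.get("population", pd.Series("?", index=sub.index))],
        level="accession",
    )


def panel_from_populations(
    Q: QMatrix, geo: pd.DataFrame, exclude: str | None = None
) -> ReferencePanel:
    """Population-level panel: mean admixture vector and geographic centroid.

    ``exclude`` drops one sample before averaging (the leave-one-out
    adjusted mean); its population's unit is recomputed from the
    remaining members.  A unit's country label is the modal country of
    its members.
    """
    geo = validate_geo_table(geo)
    if "population" not in geo.columns:
        raise ValueError("geo table must carry a 'population' column")
    df = geo.set_index("sample_id")
    ids = [s for s in Q.sample_ids if s in df.index and s != exclude]
    Qr = Q.reorder(ids)
    sub = df.loc[ids]
    units, thetas, lats, lons, countries, pops, sizes = [], [], [], [], [], [], []
    for pop, grp in sub.groupby("population", sort=True):
        rows = [ids.index(s) for s in grp.index]
        units.append(str(pop))
        thetas.append(Qr.theta[rows].mean(axis=0))
        lats.append(grp["latitude"].mean())
        lons.append(grp["longitude"].mean())
        countries.append(str(grp["country"].mode().iloc[0]) if "country" in grp else "?")
        pops.append(str(pop))
        sizes.append(len(rows))
    theta = np.vstack(thetas)
    theta = theta / theta.sum(axis=1, keepdims=True)
    return ReferencePanel(units, theta, np.array(lats), np.array(lons),
                          countries, pops, level="population",
                          n_members=np.array(sizes))


def loo_cross_validate(
    geo: pd.DataFrame,
    Q: QMatrix,
    cal: CalibrationModel,
    level: str = "population",
    M: int = 10,
) -> LooSummary:
    """Leave-one-out geolocation validation.

    Each sample is removed, the panel rebuilt without it (at population
    level, its population's mean admixture vector and centroid are
    recomputed from the remaining members), its location predicted, and
    the geographic error plus a correct-country flag recorded.  Country
    correctness uses the country label of the panel unit nearest (great
    circle) to the predicted point — a proxy that avoids polygon
    shapefiles.
    """
    geo = validate_geo_table(geo)
    df = geo.set_index("sample_id")
    records = []
    if level == "population":
        sizes = geo.groupby("population")["sample_id"].count()
        singletons = sizes[sizes < 2].index.tolist()
        if singletons:
            if len(singletons) == len(sizes):
                raise ValueError("all populations are singletons; leave-one-out undefined")
            warnings.warn(f"skipping singleton populations: {singletons}")
    for sid in Q.sample_ids:
        if sid not in df.index:
            continue
        row = df.loc[sid]
        if level == "population":
            if row["population"] in (singletons if singletons else []):
                continue
            panel = panel_from_populations(Q, geo, exclude=sid)
        elif level == "accession":
            keep = [s for s in Q.sample_ids if s != sid and s in df.index]
            panel = panel_from_accessions(Q.reorder(keep), geo)
        else:
            raise ValueError("level must be 'population' or 'accession'")
        qvec = Q.theta[Q.sample_ids.index(sid)]
        res = predict_location(qvec, panel, cal, M=M, sample_id=sid)
        if cal.metric == "great-circle-km":
            err = _haversine(res.latitude, res.longitude, row["latitude"], row["longitude"])
        else:
            err = float(np.hypot(res.latitude - row["latitude"],
                                 res.longitude - row["longitude"]))
        d_units = _haversine_matrix(
            np.concatenate([[res.latitude], panel.latitude]),
            np.concatenate([[res.longitude], panel.longitude]),
        )[0, 1:]
        nearest_country = panel.country[int(np.argmin(d_units))]
        records.append(
            {
                "sample_id": sid,
                "population": str(row.get("population", "?")),
                "error": err,
                "correct_country": str(row.get("country", "?")) == nearest_country,
            }
        )
    per_sample = pd.DataFrame(records)
    per_pop = per_sample.groupby("population")["correct_country"].mean()
    return LooSummary(
        per_sample,
        float(per_sample["error"].median()),
        float(per_sample["correct_country"].mean()),
        per_pop,
        metric=cal.metric,
    )


def select_k(loo_by_K: dict[int, LooSummary], tol: float = 0.05) -> tuple[int, pd.DataFrame]:
    """Most parsimonious K jointly minimizing error and maximizing accuracy.

    K* is the smallest K whose median error is within (1 + tol) of the
    global minimum AND whose country accuracy is within (1 - tol) of the
    global maximum.  If no K satisfies both, the argmin of the median
    error is returned with a warning.
    """
    if len(loo_by_K) < 2:
        raise ValueError("need leave-one-out summaries for at least two K values")
    table = pd.DataFrame(
        {
            "K": sorted(loo_by_K),
            "median_error": [loo_by_K[k].median_error for k in sorted(loo_by_K)],
            "country_accuracy": [loo_by_K[k].country_accuracy for k in sorted(loo_by_K)],
        }
    ).set_index("K")
    best_err = table["median_error"].min()
    best_acc = table["country_accuracy"].max()
    ok = (table["median_error"] <= (1 + tol) * best_err) & (
        table["country_accuracy"] >= (1 - tol) * best_acc
    )
    if ok.any():
        return int(table.index[ok][0]), table
    warnings.warn("no K satisfies both criteria; falling back to the error argmin")
    return int(table["median_error"].idxmin()), table
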