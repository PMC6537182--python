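"""Core in-memory containers shared across the pipeline.

Two array-backed containers carry the genetic data: :class:`GenotypeMatrix`
(per-sample allelic dosages) and :class:`QMatrix` (per-sample admixture
proportions).  Tabular per-sample metadata — coordinates, traits,
environmental covariates — travels as plain :class:`pandas.DataFrame`
objects with documented column conventions (see :mod:`whogem.genotype_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "QMatrix", "validate_geo_table"]


@dataclass
class GenotypeMatrix:
    """N x M matrix of alternate-allele dosages.

    Dosages are stored as floats so missing calls can be NaN; observed
    entries are restricted to {0, 1, 2}.  ``chrom``/``pos`` are optional
    per-variant annotations (positions are 1-based, as on disk).
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("observed dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def imputed(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by the column mean.

        Used only for regression/PCA/kinship computations; the stored
        matrix keeps its missing entries.
        """
        X = self.dosage.copy()
        if np.isnan(X).any():
            col_mean = np.nanmean(X, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(X))
            X[idx] = col_mean[idx[1]]
        return X

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=[self.variant_ids[j] for j in keep],
            dosage=self.dosage[:, keep],
            chrom=None if self.chrom is None else np.asarray(self.chrom)[keep],
            pos=None if self.pos is None else np.asarray(self.pos)[keep],
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in keep],
            variant_ids=list(self.variant_ids),
            dosage=self.dosage[keep, :],
            chrom=self.chrom,
            pos=self.pos,
        )


@dataclass
class QMatrix:
    """N x K admixture proportions; each row lies on the probability simplex."""

    sample_ids: list[str]
    theta: np.ndarray
    component_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[0] != len(self.sample_ids):
            raise ValueError("theta must be N x K with one row per sample id")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if (self.theta < -1e-12).any() or (self.theta > 1 + 1e-12).any():
            raise ValueError("admixture proportions must lie in [0, 1]")
        row_sums = self.theta.sum(axis=1)
        if np.abs(row_sums - 1.0).max() > 1e-8:
            bad = int(np.abs(row_sums - 1.0).argmax())
            raise ValueError(
                f"row {bad} ({self.sample_ids[bad]}) sums to {row_sums[bad]:.10f}, not 1"
            )
        if not self.component_names:
            self.component_names = [f"K{k + 1}" for k in range(self.theta.shape[1])]
        elif len(self.component_names) != self.theta.shape[1]:
            raise ValueError("component_names length must equal K")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def K(self) -> int:
        return self.theta.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.theta, columns=self.component_names)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def reorder(self, sample_ids: list[str]) -> "QMatrix":
        """Return a copy with rows rearranged to match ``sample_ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"sample ids absent from Q matrix: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return QMatrix(list(sample_ids), self.theta[rows], list(self.component_names))


def validate_geo_table(geo: pd.DataFrame) -> pd.DataFrame:
    """Check a geographic metadata table (sample_id, latitude, longitude, ...)."""
    for col in ("sample_id", "latitude", "longitude"):
        if col not in geo.columns:
            raise ValueError(f"geo table missing required column {col!r}")
    if geo["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in geo table")
    lat = geo["latitude"].to_numpy(float)
    lon = geo["longitude"].to_numpy(float)
    if (np.abs(lat) > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (np.abs(lon) > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    return geo
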