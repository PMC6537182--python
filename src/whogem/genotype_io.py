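"""Readers, writers and SNP filtering.

Formats: VCF (biallelic SNPs, via cyvcf2), dosage TSV (header row of
variant ids, one row per sample), ADMIXTURE-style .Q (whitespace-separated
proportions, no header, companion .id file), and CSV metadata tables.

Filtering follows common GWAS practice: per-variant missingness and
minor-allele-frequency thresholds, then variance-inflation-factor (VIF)
based LD pruning in sliding windows.  The pruning contract is the
post-hoc bound — every window of the surviving set has max VIF below the
threshold — not concordance with any particular external tool.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, QMatrix, validate_geo_table

__all__ = [
    "read_genotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "write_vcf",
    "quality_filter",
    "ld_prune",
    "read_q_matrix",
    "write_q_matrix",
    "read_geo_table",
]

_MISSING_TOKEN = "NA"


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from a VCF (by extension) or a dosage TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    return read_dosage_tsv(path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variant_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    for rec_no, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise ValueError(
                f"record {rec_no} ({var.CHROM}:{var.POS}): only biallelic SNPs supported"
            )
        dos = np.full(len(samples), np.nan)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            if len(alleles) != 2:
                raise ValueError(
                    f"record {rec_no}: non-diploid genotype for sample {samples[i]}"
                )
            if -1 in alleles:
                continue  # missing call
            dos[i] = float(sum(1 for a in alleles if a == 1))
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        variant_ids.append(vid)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        rows.append(dos)
    dosage = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, variant_ids, dosage, np.array(chroms), np.array(positions))


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=[_MISSING_TOKEN, "."])
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column of a dosage TSV must be 'sample_id'")
    sample_ids = df["sample_id"].tolist()
    variant_ids = list(df.columns[1:])
    dosage = df.iloc[:, 1:].to_numpy(float)
    return GenotypeMatrix(sample_ids, variant_ids, dosage)


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(G.dosage, columns=G.variant_ids)
    df.insert(0, "sample_id", G.sample_ids)
    with np.errstate(invalid="ignore"):
        for c in G.variant_ids:
            df[c] = df[c].map(lambda v: _MISSING_TOKEN if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only, unphased diploid genotypes."""
    chrom = G.chrom if G.chrom is not None else np.array(["1"] * G.n_variants)
    pos = G.pos if G.pos is not None else np.arange(1, G.n_variants + 1)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(str(c) for c in chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.sample_ids) + "\n")
        for j, vid in enumerate(G.variant_ids):
            gts = "\t".join(
                "./." if np.isnan(v) else gt_map[v] for v in G.dosage[:, j]
            )
            fh.write(f"{chrom[j]}\t{int(pos[j])}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def quality_filter(
    G: GenotypeMatrix, max_missing: float = 0.05, min_maf: float = 0.01
) -> GenotypeMatrix:
    """Drop variants with too many missing calls or too low a MAF."""
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    miss = np.isnan(G.dosage).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(G.dosage, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (miss <= max_missing) & (maf >= min_maf)
    if not keep.any():
        warnings.warn("quality_filter removed every variant")
    return G.subset_variants(keep)


def _vif_diag(X: np.ndarray) -> np.ndarray:
    """VIF of every column of a standardized design (diag of inverse correlation)."""
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    try:
        inv = np.linalg.inv(R)
        diag = np.diag(inv).copy()
        if (diag < 0.99).any():  # numerically broken inverse
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(R, rcond=1e-10)
        diag = np.diag(inv).copy()
        # perfectly collinear columns get infinite VIF; flag the whole
        # null-space support so one gets removed deterministically
        w, V = np.linalg.eigh(R)
        null = np.abs(w) < 1e-10
        if null.any():
            support = (np.abs(V[:, null]) > 1e-8).any(axis=1)
            diag[support] = np.inf
    return diag


def ld_prune(
    G: GenotypeMatrix, window: int = 300, step: int = 60, vif_threshold: float = 1.3
) -> GenotypeMatrix:
    """Sliding-window VIF pruning.

    Within each window of ``window`` surviving variants (advancing by
    ``step``), the variant with the largest VIF is removed repeatedly —
    ties and exact duplicates resolved by keeping the lowest index —
    until all VIFs fall below ``vif_threshold``.  Removals are global.
    Passes repeat until stable, so the result is idempotent and every
    window of the surviving set meets the bound.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 1 <= step <= window:
        raise ValueError("step must satisfy 1 <= step <= window")
    if vif_threshold <= 1:
        raise ValueError("vif_threshold must exceed 1")

    X_full = G.imputed()
    sd = X_full.std(axis=0)
    surviving = list(range(G.n_variants))
    # monomorphic columns carry no LD information; keep them out of the maths
    informative = set(np.flatnonzero(sd > 0).tolist())

    changed = True
    while changed:
        changed = False
        start = 0
        while start < len(surviving):
            while True:
                win = [j for j in surviving[start : start + window] if j in informative]
                if len(win) < 2:
                    break
                vifs = _vif_diag(X_full[:, win])
                top = vifs.max()
                if not (top >= vif_threshold or np.isinf(top)):
                    break
                # among tied-worst variants remove the highest index, so a
                # duplicate pair keeps its lowest-index member
                tied = np.flatnonzero(
                    np.isinf(vifs) if np.isinf(top) else vifs >= top * (1 - 1e-12)
                )
                surviving.remove(win[int(tied[-1])])
                changed = True
            start += step
    return G.subset_variants(np.array(surviving, dtype=int))


def read_q_matrix(path: str | Path, id_path: str | Path | None = None) -> QMatrix:
    """Read an ADMIXTURE-style .Q file (rows renormalized if off by <= 1e-6)."""
    theta = np.atleast_2d(np.loadtxt(path))
    if (theta < 0).any() or (theta > 1).any():
        raise ValueError(f"{path}: proportions outside [0, 1]")
    row_sums = theta.sum(axis=1)
    bad = np.abs(row_sums - 1.0) > 1e-6
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: row {row + 1} sums to {row_sums[row]:.8f} (deviates from 1 by more than 1e-6)"
        )
    theta = theta / row_sums[:, None]
    if id_path is None:
        candidate = Path(path).with_suffix(".id")
        id_path = candidate if candidate.exists() else None
    if id_path is not None:
        sample_ids = [line.strip() for line in open(id_path) if line.strip()]
        if len(sample_ids) != theta.shape[0]:
            raise ValueError("id file length does not match .Q row count")
    else:
        sample_ids = [f"S{i:04d}" for i in range(theta.shape[0])]
    return QMatrix(sample_ids, theta)


def write_q_matrix(Q: QMatrix, path: str | Path, id_path: str | Path | None = None) -> None:
    # round to 6 decimals, then absorb the rounding residual into each
    # row's largest entry so the written rows still sum to exactly 1
    theta = np.round(Q.theta, 6)
    resid = 1.0 - theta.sum(axis=1)
    top = Q.theta.argmax(axis=1)
    theta[np.arange(theta.shape[0]), top] += resid
    np.savetxt(path, theta, fmt="%.6f")
    if id_path is None:
        id_path = Path(path).with_suffix(".id")
    with open(id_path, "w") as fh:
        fh.write("\n".join(Q.sample_ids) + "\n")


def read_geo_table(path: str | Path) -> pd.DataFrame:
    geo = pd.read_csv(path, dtype={"sample_id": str})
    return validate_geo_table(geo)
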