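"""Diversity, differentiation, covariance, distance and ordination statistics.

All operations work on hard diploid dosages (0/1/2 with NaN missing) from
:class:`landgen.genio.GenotypeMatrix`. Missing data is handled
pairwise-complete wherever two samples are compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

__all__ = [
    "EARTH_RADIUS_KM",
    "expected_heterozygosity",
    "nucleotide_diversity",
    "wc_fst",
    "genotype_covariance",
    "gower_distance",
    "pca",
    "mantel_test",
    "geo_distance",
    "geo_distance_matrix",
    "diversity_report",
]

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# diversity


def _per_locus_gene_diversity(dosages: np.ndarray) -> np.ndarray:
    """Sample-size corrected gene diversity (2N/(2N-1))(1 - p^2 - q^2) per
    locus; NaN where fewer than 2 diploids have data."""
    n = np.sum(~np.isnan(dosages), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosages, axis=0) / (2.0 * n)
    h = np.full(dosages.shape[1], np.nan)
    ok = n >= 2
    twon = 2.0 * n[ok]
    pq = p[ok]
    h[ok] = (twon / (twon - 1.0)) * (1.0 - pq**2 - (1.0 - pq) ** 2)
    return h


def expected_heterozygosity(gm: GenotypeMatrix) -> float:
    """Mean over usable loci of the corrected per-locus gene diversity.

    A locus is usable when at least two diploids have non-missing calls;
    all-missing and single-sample loci are excluded from the average.
    """
    h = _per_locus_gene_diversity(gm.dosages)
    usable = ~np.isnan(h)
    if not usable.any():
        raise ValueError("no locus has >=2 non-missing diploid calls")
    return float(np.mean(h[usable]))


def nucleotide_diversity(gm: GenotypeMatrix, total_sites: int) -> float:
    """Per-site nucleotide diversity.

    Sums corrected per-locus heterozygosity ``2pq * 2N/(2N-1)`` over variant
    loci and divides by ``total_sites`` (monomorphic sites contribute zero).
    The sample-size correction makes the value equal to the average pairwise
    difference per site between sampled chromosomes.
    """
    if total_sites < gm.n_loci:
        raise ValueError(
            f"total_sites={total_sites} is smaller than the variant count {gm.n_loci}"
        )
    h = _per_locus_gene_diversity(gm.dosages)
    return float(np.nansum(h) / total_sites)


def diversity_report(gm: GenotypeMatrix, loc: pd.DataFrame,
                     total_sites: int | None = None) -> pd.DataFrame:
    """Per-locality H_e (and pi when ``total_sites`` is given).

    Localities with fewer than 2 samples are flagged (``flag`` column) rather
    than dropped; their statistics are NaN.
    """
    rows = []
    for locality, sub in loc.groupby("locality"):
        keep = [s for s in sub["sample"] if s in gm.samples]
        row: dict = {"locality": locality, "n_samples": len(keep), "flag": ""}
        if len(keep) < 2:
            row["flag"] = "lt2_samples"
            row["he"] = np.nan
            if total_sites is not None:
                row["pi"] = np.nan
        else:
            sub_gm = gm.subset_samples(keep)
            try:
                row["he"] = expected_heterozygosity(sub_gm)
            except ValueError:
                row["he"] = np.nan
                row["flag"] = "no_usable_loci"
            if total_sites is not None:
                row["pi"] = nucleotide_diversity(sub_gm, total_sites)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differentiation


def wc_fst(gm: GenotypeMatrix, labels: list[str] | np.ndarray) -> float:
    """Multi-locus Weir & Cockerham (1984) theta, as the ratio of summed
    variance components sum(a) / sum(a + b + c) over loci.

    ``labels`` assigns each sample to a group. Loci where fewer than two
    groups have >=1 genotyped diploid, or where the mean sample size is <= 1,
    are skipped.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != gm.n_samples:
        raise ValueError("labels length must equal sample count")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for F_ST")
    G = gm.dosages
    # per group x locus: sample size, allele freq, observed het proportion
    n_i, p_i, h_i = [], [], []
    for g in groups:
        sub = G[labels == g]
        n = np.sum(~np.isnan(sub), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = np.nanmean(sub, axis=0) / 2.0
            het = np.nanmean(sub == 1.0, axis=0)
        n_i.append(n)
        p_i.append(p)
        h_i.append(np.where(n > 0, het, np.nan))
    n_i = np.array(n_i)      # (r, L)
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    informative = (n_i > 0).sum(axis=0) >= 2
    n_i = np.where(n_i > 0, n_i, np.nan)

    r = np.sum(~np.isnan(n_i), axis=0).astype(float)     # groups with data per locus
    nbar = np.nanmean(n_i, axis=0)
    sum_n = np.nansum(n_i, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (sum_n - np.nansum(n_i**2, axis=0) / sum_n) / (r - 1.0)
        pbar = np.nansum(n_i * p_i, axis=0) / sum_n
        s2 = np.nansum(n_i * (p_i - pbar) ** 2, axis=0) / ((r - 1.0) * nbar)
        hbar = np.nansum(n_i * h_i, axis=0) / sum_n

        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0

    total = a + b + c
    ok = informative & (nbar > 1) & np.isfinite(total) & np.isfinite(a)
    if int(ok.sum()) == 0:
        raise ValueError("no locus has >=2 informative groups")
    denom = float(np.sum(total[ok]))
    if denom == 0.0:
        raise ValueError("total variance component is zero across usable loci")
    return float(np.sum(a[ok]) / denom)


# ---------------------------------------------------------------------------
# covariance / distance / ordination


@dataclass
class CovarianceMatrix:
    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8, equal_nan=True):
            raise ValueError("covariance must be symmetric")
        if not np.isfinite(np.diag(self.values)).all():
            raise ValueError("covariance diagonal must be finite")


@dataclass
class DistanceMatrix:
    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


def genotype_covariance(gm: GenotypeMatrix, standardize: bool = True) -> CovarianceMatrix:
    """Genomic relationship matrix between samples.

    ``C_ij = (1/L_ij) * sum_l (g_il - 2p_l)(g_jl - 2p_l) / (2 p_l (1 - p_l))``
    with the sum over loci where both samples are genotyped (``L_ij`` the
    per-pair count) and ``p_l`` the overall alternate-allele frequency.
    Loci with MAF 0 (or all-missing) are excluded. With
    ``standardize=False`` the per-locus variance divisor is dropped.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    p = gm.allele_freq()
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise ValueError("all loci excluded (monomorphic or missing)")
    G = gm.dosages[:, keep]
    p = p[keep]
    X = G - 2.0 * p
    if standardize:
        X = X / np.sqrt(2.0 * p * (1.0 - p))
    obs = ~np.isnan(X)
    X0 = np.where(obs, X, 0.0)
    counts = obs.astype(float) @ obs.astype(float).T
    if (counts == 0).any():
        bad = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"samples {gm.samples[bad[0]]!r} and {gm.samples[bad[1]]!r} share no genotyped locus"
        )
    C = (X0 @ X0.T) / counts
    C = (C + C.T) / 2.0
    return CovarianceMatrix(C, list(gm.samples))


def gower_distance(cov: CovarianceMatrix, sqrt: bool = False,
                   atol: float = 1e-8) -> DistanceMatrix:
    """Gower transform ``D_ij = C_ii + C_jj - 2 C_ij`` of a covariance matrix.

    The result is a squared-Euclidean distance for any PSD input; pass
    ``sqrt=True`` to return the Euclidean root instead. Small negative values
    (possible with pairwise-complete covariances) are clipped to zero with a
    warning.
    """
    C = cov.values
    if not np.allclose(C, C.T, atol=atol):
        raise ValueError("covariance asymmetric beyond tolerance")
    d = np.diag(C)
    D = d[:, None] + d[None, :] - 2.0 * C
    np.fill_diagonal(D, 0.0)
    n_neg = int((D < 0).sum())
    if n_neg:
        warnings.warn(f"clipped {n_neg} negative Gower distances to 0", stacklevel=2)
        D = np.clip(D, 0.0, None)
    if sqrt:
        D = np.sqrt(D)
    return DistanceMatrix(D, list(cov.samples))


def pca(cov: CovarianceMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of a sample covariance matrix.

    Returns ``(eigenvalues desc, axes, variance fractions)`` where axes are
    orthonormal columns and fraction i is ``max(lambda_i, 0) / sum_j
    max(lambda_j, 0)``.
    """
    vals, vecs = np.linalg.eigh(cov.values)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    pos = np.clip(vals, 0.0, None)
    total = pos.sum()
    fractions = pos / total if total > 0 else np.zeros_like(pos)
    return vals, vecs, fractions


# ---------------------------------------------------------------------------
# distance-matrix association


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
                seed: int | None = None) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with a one-sided
    (greater) permutation p-value.

    r is the Pearson correlation over strictly-lower-triangle entries;
    permutations jointly shuffle the rows and columns of the second matrix.
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``.
    """
    if d1.values.shape != d2.values.shape:
        raise ValueError("distance matrices must have matching shapes")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = d1.values.shape[0]
    il = np.tril_indices(n, k=-1)
    x = d1.values[il]
    y = d2.values[il]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = d2.values[np.ix_(perm, perm)][il]
        sd = yp.std()
        if sd == 0:
            continue
        r_perm = float(np.mean(xc * (yp - yp.mean()) / sd))
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return r_obs, p


# ---------------------------------------------------------------------------
# geography


def geo_distance(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in km (Earth radius 6371.0088 km).

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, dtype=float),
                                              np.asarray(lon1, dtype=float),
                                              np.asarray(lat2, dtype=float),
                                              np.asarray(lon2, dtype=float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def geo_distance_matrix(lat: np.ndarray, lon: np.ndarray,
                        ids: list[str] | None = None) -> DistanceMatrix:
    """All-pairs haversine distances (km) for a set of points."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    D = geo_distance(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    D = np.asarray(D)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    if ids is None:
        ids = [str(i) for i in range(len(lat))]
    return DistanceMatrix(D, list(ids))
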