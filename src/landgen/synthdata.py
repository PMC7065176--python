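"""Synthetic landscapes with known ground truth.

Two generators feed the pipeline:

* :func:`simulate_landscape` — localities on a latitudinal gradient, per-locus
  locality allele frequencies perturbed on the logit scale by a Gaussian
  process whose covariance combines a geographic kernel (isolation by
  distance) and an environmental kernel over causal variables (isolation by
  environment); diploid dosages are binomial draws from the locality
  frequency.
* :func:`simulate_linked_genotypes` — founder-mosaic haplotypes along one
  chromosome, with a per-base switch probability controlling the range of
  linkage disequilibrium.

Both are fully determined by an explicit integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genio import GenotypeMatrix
from .lddecay import hill_weir_expectation
from .popgen import geo_distance

__all__ = [
    "LandscapeTruth",
    "LDSimTruth",
    "EnvVariable",
    "DEFAULT_BOX",
    "default_variables",
    "simulate_environment",
    "simulate_landscape",
    "simulate_linked_genotypes",
    "hill_weir_synthetic_pairs",
    "write_truth",
]

# north-south elongated box in south-eastern Australia (lat_min, lat_max, lon_min, lon_max)
DEFAULT_BOX = (-37.0, -28.0, 146.0, 151.0)


@dataclass(frozen=True)
class EnvVariable:
    name: str
    category: str
    spatial_scale: float | None = None  # km; None => pure i.i.d. noise

    def __post_init__(self):
        if not self.category:
            raise ValueError("category must be a non-empty string")


def default_variables() -> list[EnvVariable]:
    """A small catalogue mixing spatially structured variables and noise
    decoys across the three conventional categories."""
    return [
        EnvVariable("precip_ann", "Water", 400.0),
        EnvVariable("water_noise", "Water", None),
        EnvVariable("temp_max", "Energy", 500.0),
        EnvVariable("energy_noise", "Energy", None),
        EnvVariable("soil_p", "Soil", 300.0),
        EnvVariable("soil_noise", "Soil", None),
    ]


@dataclass
class LandscapeTruth:
    """Ground-truth record for a simulated landscape."""

    locality_ids: list[str]
    lat: list[float]
    lon: list[float]
    ancestral_freqs: list[float]
    sigma2_geo: float
    phi_geo: float
    sigma2_env: float
    phi_env: float
    causal_ids: list[str]
    seed: int

    def __post_init__(self):
        if self.sigma2_geo < 0 or self.sigma2_env < 0:
            raise ValueError("variance magnitudes must be >= 0")
        f = np.asarray(self.ancestral_freqs)
        if ((f <= 0) | (f >= 1)).any():
            raise ValueError("ancestral frequencies must lie in (0,1)")


@dataclass
class LDSimTruth:
    """Parameters of the founder-mosaic linked-genotype simulation."""

    n_founders: int
    switch_prob: float       # per base
    snp_density: float       # SNPs per bp
    chrom_length: int        # bp
    n_diploids: int
    seed: int
    positions: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 < self.switch_prob < 1.0):
            raise ValueError("switch probability must lie in (0,1)")
        if self.n_founders < 2:
            raise ValueError("need >= 2 founder haplotypes")
        if self.n_diploids < 2:
            raise ValueError("need >= 2 diploid samples")
        pos = np.asarray(self.positions)
        if len(pos) and (np.diff(pos) <= 0).any():
            raise ValueError("positions must be strictly increasing")


def _exp_kernel(D: np.ndarray, sigma2: float, phi: float) -> np.ndarray:
    if sigma2 == 0.0:
        return np.zeros_like(D)
    return sigma2 * np.exp(-D / phi)


def _locality_coords(n: int, rng: np.random.Generator,
                     box: tuple[float, float, float, float]) -> tuple[np.ndarray, np.ndarray]:
    lat_min, lat_max, lon_min, lon_max = box
    lat = rng.uniform(lat_min, lat_max, n)
    lon = rng.uniform(lon_min, lon_max, n)
    return lat, lon


def simulate_environment(n_localities: int,
                         variables: list[EnvVariable],
                         seed: int,
                         coords: tuple[np.ndarray, np.ndarray] | None = None,
                         box: tuple[float, float, float, float] = DEFAULT_BOX,
                         ) -> pd.DataFrame:
    """Locality-level environment table (long format).

    Spatially structured variables are drawn from a zero-mean Gaussian field
    with exponential covariance ``exp(-d/scale)`` over great-circle locality
    distances; ``spatial_scale=None`` variables are i.i.d. standard normal.
    Every variable is standardized to mean 0, variance 1 across localities.
    """
    if n_localities <= 0:
        raise ValueError("need at least one locality")
    if not variables:
        raise ValueError("need at least one variable")
    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names")
    rng = np.random.default_rng(seed)
    if coords is None:
        lat, lon = _locality_coords(n_localities, rng, box)
    else:
        lat, lon = map(np.asarray, coords)
    D = geo_distance(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    rows = []
    for v in variables:
        if v.spatial_scale is None:
            x = rng.standard_normal(n_localities)
        else:
            K = np.exp(-np.asarray(D) / v.spatial_scale) + 1e-8 * np.eye(n_localities)
            L = np.linalg.cholesky(K)
            x = L @ rng.standard_normal(n_localities)
        sd = x.std()
        x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        for i in range(n_localities):
            rows.append({"locality": f"L{i:03d}", "variable": v.name,
                         "category": v.category, "value": x[i]})
    return pd.DataFrame(rows)


def simulate_landscape(n_localities: int,
                       n_per_locality: int | tuple[int, int],
                       n_loci: int,
                       ibd: dict,
                       ibe: dict,
                       seed: int,
                       variables: list[EnvVariable] | None = None,
                       box: tuple[float, float, float, float] = DEFAULT_BOX,
                       ) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, LandscapeTruth]:
    """Simulate a structured landscape with known IBD and IBE strengths.

    Parameters
    ----------
    ibd
        ``{"sigma2": sigma2_geo, "phi": phi_geo}`` — magnitude and range (km)
        of the geographic kernel.
    ibe
        ``{"sigma2": sigma2_env, "phi": phi_env, "causal_ids": [...]}`` —
        magnitude and range of the environmental kernel over the Euclidean
        distance between standardized causal-variable profiles.
    n_per_locality
        Fixed count or an inclusive ``(low, high)`` range sampled per
        locality.

    Per-locus locality deviations on the logit-frequency scale are a
    zero-mean multivariate normal with covariance
    ``sigma2_geo * exp(-d_geo/phi_geo) + sigma2_env * exp(-d_env/phi_env)``;
    dosages are Binomial(2, locality frequency).
    """
    if n_localities < 3:
        raise ValueError("need at least 3 localities")
    if n_loci < 1:
        raise ValueError("need at least one locus")
    if variables is None:
        variables = default_variables()
    sigma2_geo = float(ibd.get("sigma2", 0.0))
    phi_geo = float(ibd.get("phi", 1.0))
    sigma2_env = float(ibe.get("sigma2", 0.0))
    phi_env = float(ibe.get("phi", 1.0))
    causal_ids = list(ibe.get("causal_ids", []))
    var_names = {v.name for v in variables}
    unknown = set(causal_ids) - var_names
    if unknown:
        raise ValueError(f"causal ids not among variables: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    lat, lon = _locality_coords(n_localities, rng, box)
    env = simulate_environment(
        n_localities, variables, seed=int(rng.integers(2**31)), coords=(lat, lon))
    loc_ids = [f"L{i:03d}" for i in range(n_localities)]

    d_geo = np.asarray(geo_distance(lat[:, None], lon[:, None], lat[None, :], lon[None, :]))
    if causal_ids and sigma2_env > 0:
        wide = env.pivot(index="locality", columns="variable", values="value")
        X = wide.loc[loc_ids, causal_ids].to_numpy()
        d_env = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    else:
        d_env = np.zeros_like(d_geo)

    K = _exp_kernel(d_geo, sigma2_geo, phi_geo) + _exp_kernel(d_env, sigma2_env, phi_env)
    K += 1e-8 * np.eye(n_localities)
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "locality covariance not positive definite after jitter "
            f"(sigma2_geo={sigma2_geo}, phi_geo={phi_geo}, "
            f"sigma2_env={sigma2_env}, phi_env={phi_env})"
        ) from exc

    p0 = rng.uniform(0.1, 0.9, n_loci)
    if sigma2_geo > 0 or sigma2_env > 0:
        dev = L @ rng.standard_normal((n_localities, n_loci))
    else:
        dev = np.zeros((n_localities, n_loci))
    freqs = expit(logit(p0)[None, :] + dev)   # locality x locus

    if isinstance(n_per_locality, tuple):
        lo, hi = n_per_locality
        counts = rng.integers(lo, hi + 1, n_localities)
    else:
        counts = np.full(n_localities, int(n_per_locality))
    sample_ids, sample_loc, dosage_rows = [], [], []
    for i, loc_id in enumerate(loc_ids):
        for k in range(counts[i]):
            sample_ids.append(f"{loc_id}_s{k:02d}")
            sample_loc.append(loc_id)
            dosage_rows.append(rng.binomial(2, freqs[i]).astype(float))
    loci = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, n_loci + 1) * 1000,
        "ref": "A",
        "alt": "T",
    })
    gm = GenotypeMatrix(sample_ids, loci, np.vstack(dosage_rows))
    loc_table = pd.DataFrame({
        "sample": sample_ids,
        "locality": sample_loc,
        "lat": [lat[loc_ids.index(l)] for l in sample_loc],
        "lon": [lon[loc_ids.index(l)] for l in sample_loc],
    })
    truth = LandscapeTruth(
        locality_ids=loc_ids, lat=lat.tolist(), lon=lon.tolist(),
        ancestral_freqs=p0.tolist(), sigma2_geo=sigma2_geo, phi_geo=phi_geo,
        sigma2_env=sigma2_env, phi_env=phi_env, causal_ids=causal_ids, seed=seed,
    )
    return gm, loc_table, env, truth


def simulate_linked_genotypes(truth: LDSimTruth) -> tuple[GenotypeMatrix, LDSimTruth]:
    """Mosaic-of-founders haplotype simulation along one chromosome.

    Founder haplotypes carry independent biallelic SNPs at frequencies drawn
    uniformly from (0.2, 0.8). Each sampled haplotype copies a founder and,
    between adjacent SNPs separated by g bases, switches to a uniformly chosen
    founder with probability ``1 - (1 - switch_prob)^g``. Diploids pair
    consecutive sampled haplotypes; dosage is the haplotype sum.
    """
    rng = np.random.default_rng(truth.seed)
    n_snps = int(round(truth.snp_density * truth.chrom_length))
    if n_snps < 2:
        raise ValueError(
            f"snp_density={truth.snp_density} on {truth.chrom_length} bp yields "
            f"{n_snps} SNPs; need >= 2"
        )
    positions = np.sort(rng.choice(np.arange(1, truth.chrom_length + 1),
                                   size=n_snps, replace=False))
    founder_freq = rng.uniform(0.2, 0.8, n_snps)
    founders = (rng.random((truth.n_founders, n_snps)) < founder_freq).astype(np.int8)

    gaps = np.diff(positions)
    p_switch = 1.0 - (1.0 - truth.switch_prob) ** gaps
    n_hap = 2 * truth.n_diploids
    haps = np.empty((n_hap, n_snps), dtype=np.int8)
    for h in range(n_hap):
        idx = int(rng.integers(truth.n_founders))
        haps[h, 0] = founders[idx, 0]
        switches = rng.random(n_snps - 1) < p_switch
        for j in range(1, n_snps):
            if switches[j - 1]:
                idx = int(rng.integers(truth.n_founders))
            haps[h, j] = founders[idx, j]
    dosages = (haps[0::2] + haps[1::2]).astype(float)
    loci = pd.DataFrame({
        "chrom": "chr1", "pos": positions.astype(int), "ref": "A", "alt": "T",
    })
    samples = [f"d{i:03d}" for i in range(truth.n_diploids)]
    out_truth = LDSimTruth(
        truth.n_founders, truth.switch_prob, truth.snp_density,
        truth.chrom_length, truth.n_diploids, truth.seed,
        positions=positions.astype(int).tolist(),
    )
    return GenotypeMatrix(samples, loci, dosages), out_truth


def hill_weir_synthetic_pairs(rho: float, n: int, distances,
                              noise_sd: float = 0.0,
                              seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Noisy (distance, r^2) pairs lying on the decay expectation curve.

    With ``noise_sd=0`` the points are exact curve values; otherwise Gaussian
    noise is added and the result clipped to [0, 1].
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    if n < 4:
        raise ValueError("n must be >= 4")
    d = np.asarray(distances, dtype=float)
    if (d <= 0).any():
        raise ValueError("distances must be positive")
    r2 = hill_weir_expectation(rho * d, n)
    r2 = np.atleast_1d(np.asarray(r2, dtype=float))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r2 = np.clip(r2 + rng.normal(0.0, noise_sd, r2.shape), 0.0, 1.0)
    return d, r2


def write_truth(truth, path) -> None:
    """Serialize a truth record (dataclass) to JSON."""
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2)
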