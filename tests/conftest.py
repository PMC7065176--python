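import numpy as np
import pandas as pd
import pytest

from landgen.genio import GenotypeMatrix


def make_gm(dosages, samples=None, positions=None, chrom="chr1"):
    """Build a GenotypeMatrix from a plain dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    loci = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=int),
        "ref": "A", "alt": "T",
    })
    return GenotypeMatrix(samples, loci, dosages)


@pytest.fixture
def toy_gm():
    """6 samples x 4 loci, no missing data."""
    rng = np.random.default_rng(42)
    return make_gm(rng.integers(0, 3, size=(6, 4)).astype(float))


@pytest.fixture(scope="session")
def small_landscape():
    """A small simulated landscape with strong IBD, shared across tests."""
    from landgen import synthdata
    return synthdata.simulate_landscape(
        12, 4, 400, ibd={"sigma2": 1.5, "phi": 400.0},
        ibe={"sigma2": 0.0, "phi": 1.0, "causal_ids": []}, seed=7)


@pytest.fixture(scope="session")
def small_pairs(small_landscape):
    from landgen import gdmcore, popgen
    gm, loc, env, _ = small_landscape
    cov = popgen.genotype_covariance(gm)
    dist = popgen.gower_distance(cov)
    return gdmcore.build_pair_table(dist, loc, env, min_geo_km=10.0)
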