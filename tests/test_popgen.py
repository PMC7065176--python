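import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from landgen import popgen
from landgen.popgen import (CovarianceMatrix, DistanceMatrix,
                            expected_heterozygosity, genotype_covariance,
                            geo_distance, gower_distance, mantel_test,
                            nucleotide_diversity, pca, wc_fst)

from conftest import make_gm


# ---------------------------------------------------------------------------
# oracles

def he_oracle(dosages):
    """Straight per-locus evaluation of (2N/(2N-1))(1 - p^2 - q^2)."""
    vals = []
    for col in dosages.T:
        obs = col[~np.isnan(col)]
        if len(obs) < 2:
            continue
        p = obs.sum() / (2 * len(obs))
        n2 = 2 * len(obs)
        vals.append((n2 / (n2 - 1)) * (1 - p**2 - (1 - p) ** 2))
    return float(np.mean(vals))


def pi_pairwise_oracle(dosages, total_sites):
    """Average pairwise per-site difference between sampled chromosomes,
    treating each diploid as two haplotypes (valid for homozygous dosages)."""
    haps = []
    for row in dosages:
        haps.append(row / 2)
        haps.append(row / 2)
    haps = np.array(haps)
    diffs = [np.sum(np.abs(a - b)) for a, b in itertools.combinations(haps, 2)]
    return float(np.mean(diffs) / total_sites)


def wc_fst_oracle(counts_per_group):
    """WC84 theta from per-group (n_AA, n_Aa, n_aa) genotype counts at each
    locus, written directly from the 1984 variance-component definitions."""
    num = den = 0.0
    for locus in counts_per_group:
        r = len(locus)
        n_i = np.array([sum(g) for g in locus], dtype=float)
        p_i = np.array([(2 * g[0] + g[1]) / (2 * sum(g)) for g in locus])
        h_i = np.array([g[1] / sum(g) for g in locus])
        nbar = n_i.mean()
        nc = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
        pbar = (n_i * p_i).sum() / n_i.sum()
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / n_i.sum()
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


# ---------------------------------------------------------------------------
# diversity

class TestHeterozygosity:
    def test_monomorphic_contributes_zero(self):
        gm = make_gm([[0, 0], [0, 2], [0, 0], [0, 2]])
        # locus 1 is monomorphic: average is half the polymorphic-locus value
        gm_poly = gm.subset_loci(np.array([False, True]))
        assert expected_heterozygosity(gm) == pytest.approx(
            expected_heterozygosity(gm_poly) / 2)

    def test_n2_p_half_closed_form(self):
        gm = make_gm([[0], [2]])
        assert expected_heterozygosity(gm) == pytest.approx(2.0 / 3.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (6, 20)).astype(float)
        d[rng.random(d.shape) < 0.15] = np.nan
        gm = make_gm(d)
        assert expected_heterozygosity(gm) == pytest.approx(he_oracle(d))

    def test_no_usable_loci_errors(self):
        gm = make_gm([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="no locus"):
            expected_heterozygosity(gm)


class TestNucleotideDiversity:
    def test_homozygous_pair_matches_pairwise_oracle(self):
        # two homozygous samples differing at 1 of 10 sites; the corrected
        # convention equals the average pairwise chromosome difference
        gm = make_gm([[0], [2]])
        pi = nucleotide_diversity(gm, total_sites=10)
        assert pi == pytest.approx(pi_pairwise_oracle(gm.dosages, 10))
        assert pi == pytest.approx(2 * 0.25 * (4 / 3) / 10)

    def test_identical_samples_zero(self):
        gm = make_gm([[1, 2], [1, 2]])
        # het sites still contribute; use homozygous-identical matrix
        gm = make_gm([[0, 2], [0, 2]])
        assert nucleotide_diversity(gm, 10) == 0.0

    def test_sample_order_invariance(self, toy_gm):
        perm = toy_gm.subset_samples(toy_gm.samples[::-1])
        assert nucleotide_diversity(toy_gm, 50) == pytest.approx(
            nucleotide_diversity(perm, 50))

    def test_total_sites_too_small_errors(self, toy_gm):
        with pytest.raises(ValueError, match="total_sites"):
            nucleotide_diversity(toy_gm, toy_gm.n_loci - 1)


# ---------------------------------------------------------------------------
# F_ST

class TestWcFst:
    def test_fixed_differences_give_one(self):
        d = np.array([[2.0] * 3] * 5 + [[0.0] * 3] * 5)
        gm = make_gm(d)
        labels = ["A"] * 5 + ["B"] * 5
        assert wc_fst(gm, labels) == pytest.approx(1.0)

    def test_matches_direct_formula_script(self):
        # printed toy: 2 demes, 5+5 diploids, explicit genotype counts
        counts = [
            [(3, 1, 1), (0, 2, 3)],   # locus 1: (n_AA, n_Aa, n_aa) per deme
            [(2, 2, 1), (4, 1, 0)],
            [(1, 3, 1), (1, 1, 3)],
        ]
        rows_a, rows_b = [], []
        for locus in counts:
            for rows, (naa, nab, nbb) in zip((rows_a, rows_b), locus):
                rows.append([0.0] * naa + [1.0] * nab + [2.0] * nbb)
        d = np.array([list(col) for col in zip(*rows_a)]
                     + [list(col) for col in zip(*rows_b)])
        gm = make_gm(d)
        labels = ["A"] * 5 + ["B"] * 5
        assert wc_fst(gm, labels) == pytest.approx(wc_fst_oracle(counts))

    def test_panmictic_null_unbiased(self):
        rng = np.random.default_rng(1)
        n_rep = 200
        ests = np.empty(n_rep)
        for b in range(n_rep):
            p = rng.uniform(0.2, 0.8, 40)
            d = rng.binomial(2, p, size=(20, 40)).astype(float)
            gm = make_gm(d)
            labels = np.array(["A"] * 10 + ["B"] * 10)
            rng.shuffle(labels)
            ests[b] = wc_fst(gm, labels)
        se = ests.std(ddof=1) / math.sqrt(n_rep)
        assert abs(ests.mean()) < 3 * se + 1e-3

    def test_single_group_errors(self, toy_gm):
        with pytest.raises(ValueError, match="2 groups"):
            wc_fst(toy_gm, ["A"] * toy_gm.n_samples)


# ---------------------------------------------------------------------------
# covariance / distances / pca

class TestGenotypeCovariance:
    def test_identical_samples_equal_entries(self):
        gm = make_gm([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]])
        C = genotype_covariance(gm).values
        assert C[0, 0] == pytest.approx(C[0, 1])
        assert C[1, 1] == pytest.approx(C[0, 1])

    def test_hand_example(self):
        # 3 samples x 2 loci, worked by hand from the stated sum
        d = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        gm = make_gm(d)
        p = d.mean(axis=0) / 2          # (0.5, 0.5) at both loci
        X = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
        expected = X @ X.T / 2
        np.testing.assert_allclose(genotype_covariance(gm).values, expected)

    def test_locus_order_invariance(self, toy_gm):
        rng = np.random.default_rng(2)
        order = rng.permutation(toy_gm.n_loci)
        gm2 = make_gm(toy_gm.dosages[:, order])
        np.testing.assert_allclose(genotype_covariance(toy_gm).values,
                                   genotype_covariance(gm2).values)

    def test_all_monomorphic_errors(self):
        gm = make_gm([[0, 2], [0, 2]])
        with pytest.raises(ValueError, match="excluded"):
            genotype_covariance(gm)


class TestGowerDistance:
    def test_identity_covariance(self):
        D = gower_distance(CovarianceMatrix(np.eye(2), ["a", "b"])).values
        assert D[0, 1] == pytest.approx(2.0)

    def test_printed_formula(self):
        C = CovarianceMatrix(np.array([[2.0, 1.0], [1.0, 2.0]]), ["a", "b"])
        assert gower_distance(C).values[0, 1] == pytest.approx(2.0)

    def test_equals_squared_euclidean_embedding(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((5, 5))
        C = CovarianceMatrix(A @ A.T, list("abcde"))
        vals, vecs = np.linalg.eigh(C.values)
        emb = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
        expected = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2)
        np.testing.assert_allclose(gower_distance(C).values, expected, atol=1e-8)

    def test_negative_clipped_with_warning(self):
        C = CovarianceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
        with pytest.warns(UserWarning, match="clipped"):
            D = gower_distance(C)
        assert D.values[0, 1] == 0.0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            CovarianceMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]), ["a", "b"])


class TestPca:
    def test_rank_one_explains_all(self):
        v = np.array([1.0, 2.0, 3.0])
        C = CovarianceMatrix(np.outer(v, v), list("abc"))
        _, _, frac = pca(C)
        assert frac[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((6, 6))
        C = CovarianceMatrix(A @ A.T, list("abcdef"))
        vals, vecs, frac = pca(C)
        assert frac.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(vecs.T @ vecs, np.eye(6), atol=1e-10)

    def test_agrees_with_dense_solver(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((6, 6))
        C = CovarianceMatrix((A + A.T) / 2, list("abcdef"))
        vals, _, _ = pca(C)
        from scipy.linalg import eigh
        np.testing.assert_allclose(vals, eigh(C.values)[0][::-1], atol=1e-10)


# ---------------------------------------------------------------------------
# Mantel

class TestMantel:
    def _random_dist(self, rng, n=8):
        pts = rng.standard_normal((n, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        return DistanceMatrix(D, [str(i) for i in range(n)])

    def test_identical_matrices(self):
        rng = np.random.default_rng(6)
        D = self._random_dist(rng)
        r, p = mantel_test(D, D, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 100.0)

    def test_r_is_plain_pearson_on_triangle(self):
        rng = np.random.default_rng(7)
        D1, D2 = self._random_dist(rng), self._random_dist(rng)
        r, _ = mantel_test(D1, D2, n_perm=99, seed=0)
        il = np.tril_indices(8, k=-1)
        assert r == pytest.approx(np.corrcoef(D1.values[il], D2.values[il])[0, 1])

    def test_constant_matrix_errors(self):
        rng = np.random.default_rng(8)
        D1 = self._random_dist(rng)
        flat = DistanceMatrix(np.ones((8, 8)) - np.eye(8), D1.samples)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(D1, flat, n_perm=99)


# ---------------------------------------------------------------------------
# geography

class TestGeoDistance:
    def test_identical_points_zero(self):
        assert geo_distance(-30.0, 150.0, -30.0, 150.0) == 0.0

    def test_one_degree_meridian(self):
        expected = popgen.EARTH_RADIUS_KM * math.pi / 180
        assert geo_distance(0.0, 0.0, 1.0, 0.0) == pytest.approx(expected)
        assert expected == pytest.approx(111.195, abs=5e-4)

    @given(lat1=st.floats(-89, 89), lon1=st.floats(-179, 179),
           lat2=st.floats(-89, 89), lon2=st.floats(-179, 179))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, lat1, lon1, lat2, lon2):
        d1 = geo_distance(lat1, lon1, lat2, lon2)
        d2 = geo_distance(lat2, lon2, lat1, lon1)
        assert d1 == pytest.approx(d2)
        assert d1 >= 0
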