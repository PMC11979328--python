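import numpy as np
import pytest

import oracles
from conftest import random_matrix
from granatum.popgen import (
    admixture_em,
    heterozygosity,
    ld_r2,
    nucleotide_diversity,
    pca,
    per_site_pi,
    q_correlation,
    tajimas_d,
    weir_cockerham_fst,
)
from granatum.synthetic import SimConfig, pop_labels, simulate_two_pop_snps
from granatum.variant_io import MISSING, GenomeLayout, GenomicWindow, GenotypeMatrix


def _matrix(codes, pos=None, chrom=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, s = codes.shape
    pos = np.arange(s) * 10 if pos is None else pos
    chrom = ["chr1"] * s if chrom is None else chrom
    return GenotypeMatrix(
        [f"s{i}" for i in range(n)], chrom, pos, ["A"] * s, ["T"] * s, codes
    )


class TestPi:
    def test_monomorphic_window_is_zero(self):
        m = _matrix(np.zeros((4, 5)))
        out = nucleotide_diversity(m, [GenomicWindow("chr1", 0, 100)])
        assert out["value"][0] == 0.0

    def test_two_samples_opposite_homozygotes(self):
        # 4 differing haplotype pairs of 6 -> per-site pi = 4/6
        m = _matrix([[0], [2]])
        out = nucleotide_diversity(m, [GenomicWindow("chr1", 0, 1)])
        assert out["value"][0] == pytest.approx(4 / 6, rel=1e-12)

    def test_matches_pairwise_bruteforce(self):
        m = random_matrix(seed=3, n_samples=15, n_sites=80, missing_frac=0.1)
        expected = oracles.pi_per_site(m.codes)
        got = per_site_pi(m)
        for e, g in zip(expected, got):
            if np.isnan(e):
                assert np.isnan(g)
            else:
                assert g == pytest.approx(e, rel=1e-9)


class TestTajimasD:
    def test_no_segregating_sites_is_nan(self):
        m = _matrix(np.zeros((5, 4)))
        out = tajimas_d(m, [GenomicWindow("chr1", 0, 100)])
        assert np.isnan(out["value"][0])

    def test_fixed_configuration_matches_oracle(self):
        # n=10 haplotypes, 16 sites with specified alt-allele counts
        counts = [1, 1, 2, 3, 5, 5, 4, 2, 9, 1, 7, 8, 2, 6, 5, 3]
        codes = np.zeros((5, len(counts)), dtype=np.int8)
        for j, c in enumerate(counts):
            codes[: c // 2, j] = 2
            if c % 2:
                codes[c // 2, j] = 1
        m = _matrix(codes)
        out = tajimas_d(m, [GenomicWindow("chr1", 0, 1000)])
        assert out["value"][0] == pytest.approx(0.5727639997438242, rel=1e-9)
        assert out["value"][0] == pytest.approx(oracles.tajimas_d(codes), rel=1e-9)

    def test_fewer_than_four_haplotypes_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d(_matrix([[1]]), [GenomicWindow("chr1", 0, 10)])


class TestHeterozygosity:
    @pytest.mark.parametrize(
        "codes,expected",
        [(np.ones((3, 10)), 1.0), (np.full((3, 10), 2), 0.0)],
    )
    def test_extremes(self, codes, expected):
        het = heterozygosity(_matrix(codes))
        assert (het == expected).all()

    def test_counts_hets_over_nonmissing(self):
        row = [1, 1, 1, 0, 0, 2, 2, 0, 2, 0, MISSING, MISSING]
        het = heterozygosity(_matrix([row]))
        assert het.iloc[0] == pytest.approx(0.3)


class TestFst:
    def test_fixed_difference_is_one(self):
        codes = np.r_[np.zeros((10, 5)), np.full((10, 5), 2)]
        m = _matrix(codes)
        pop = np.array(["p1"] * 10 + ["p2"] * 10)
        assert weir_cockerham_fst(m, pop) == pytest.approx(1.0)

    def test_identical_pools_near_zero(self):
        m = random_matrix(seed=5, n_samples=30, n_sites=300, missing_frac=0.0)
        pop = np.array(["p1", "p2"] * 15)
        assert abs(weir_cockerham_fst(m, pop)) < 0.05

    def test_matches_scalar_oracle(self):
        m = random_matrix(seed=9, n_samples=24, n_sites=150, missing_frac=0.08)
        pop = np.array(["p1"] * 12 + ["p2"] * 12)
        got = weir_cockerham_fst(m, pop)
        exp = oracles.wc_fst_global(m.codes, list(pop))
        assert got == pytest.approx(exp, rel=1e-9)

    def test_windowed_nan_when_population_empty(self):
        codes = np.array([[0, 1], [MISSING, MISSING], [1, 1], [2, 0]], dtype=np.int8)
        m = _matrix(codes)
        pop = np.array(["p1", "p1", "p2", "p2"])
        out = weir_cockerham_fst(m, pop, [GenomicWindow("chr1", 0, 100)])
        # p1 has a single callable diploid at each site: estimator still defined
        assert out["n_sites"][0] == 2


class TestLd:
    def test_duplicated_column_r2_one(self):
        col = np.array([0, 1, 2, 0, 1, 2, 2, 0])
        m = _matrix(np.c_[col, col, 2 - col])
        pairs, _ = ld_r2(m)
        assert pairs["r2"].min() == pytest.approx(1.0)  # also anti-correlated pair

    def test_distance_cap_excludes_far_pairs(self):
        m = _matrix([[0, 1], [1, 0], [2, 2], [1, 1]], pos=[0, 250_000])
        pairs, _ = ld_r2(m, max_dist_bp=200_000)
        assert pairs.empty

    def test_matches_corrcoef_oracle(self):
        m = random_matrix(seed=21, n_samples=25, n_sites=40, missing_frac=0.1)
        pairs, _ = ld_r2(m, max_dist_bp=10**9)
        for row in pairs.itertuples():
            exp = oracles.r2_pair(m.codes[:, row.site_i], m.codes[:, row.site_j])
            assert row.r2 == pytest.approx(exp, rel=1e-9)


class TestPca:
    def test_two_populations_separate_on_pc1(self):
        cfg = SimConfig(seed=2, n_sites=1000)
        m, _ = simulate_two_pop_snps(cfg)
        coords, _ = pca(m)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(coords[:, :1], pop_labels(cfg)) > 0.5

    def test_identical_samples_zero_variance(self):
        m = _matrix(np.ones((6, 20)))
        coords, ratio = pca(m)
        assert np.allclose(coords, 0.0)

    def test_site_order_invariance(self):
        m = random_matrix(seed=4, n_samples=12, n_sites=60, missing_frac=0.0)
        perm = np.random.default_rng(0).permutation(m.n_sites)
        m2 = m.take_sites(perm)  # GenotypeMatrix re-sorts by position
        c1, _ = pca(m)
        c2, _ = pca(m2)
        assert np.allclose(np.abs(c1), np.abs(c2), atol=1e-8)


class TestAdmixture:
    def test_k1_closed_form(self):
        m = random_matrix(seed=6, n_samples=10, n_sites=50, missing_frac=0.0)
        Q, P, trace = admixture_em(m, 1)
        assert np.allclose(Q, 1.0)
        assert np.allclose(P[0], m.alt_freq(), atol=1e-9)

    def test_loglik_non_decreasing_and_simplex(self):
        m, _ = simulate_two_pop_snps(SimConfig(seed=8, n_sites=400))
        Q, P, trace = admixture_em(m, 2, seed=1)
        assert np.all(np.diff(trace) >= -1e-8)
        assert np.allclose(Q.sum(axis=1), 1.0)

    def test_k_exceeding_samples_rejected(self):
        m = random_matrix(seed=1, n_samples=4, n_sites=10)
        with pytest.raises(ValueError):
            admixture_em(m, 5)


class TestQCorrelation:
    def test_identical_vectors(self):
        q = np.linspace(0.1, 0.9, 38)
        r2, p = q_correlation(q, q)
        assert r2 == pytest.approx(1.0)

    def test_label_swap_resolved(self):
        q = np.linspace(0.1, 0.9, 38)
        r2, _ = q_correlation(q, 1.0 - q)
        assert r2 == pytest.approx(1.0)

    def test_independent_vectors_low_r2(self):
        rng = np.random.default_rng(0)
        r2, _ = q_correlation(rng.random(38), rng.random(38))
        assert r2 < 0.2
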