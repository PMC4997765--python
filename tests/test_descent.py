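import numpy as np
import pytest
from scipy import stats

from pedimpute.descent import (
    MendelianInconsistencyError,
    build_descent,
    exact_iv_posterior,
    haldane,
    locus_likelihood,
    sample_iv_mcmc,
    transition_prob,
)
from pedimpute.pedio import GeneticMap, GenotypeMatrix, Marker
from pedimpute.simdata import fig1_like_pedigree

from tests.conftest import (
    oracle_iv_marginals,
    oracle_labels,
    oracle_locus_likelihood,
    random_genotypes,
    small_pedigree_battery,
)

GMAP = GeneticMap.constant_rate()


class TestHaldane:
    def test_zero_distance(self):
        assert haldane(0.0) == 0.0

    def test_asymptote(self):
        assert haldane(1e6) == pytest.approx(0.5)

    def test_fifty_centimorgans(self):
        assert haldane(50.0) == pytest.approx((1 - np.exp(-1)) / 2)
        assert haldane(50.0) == pytest.approx(0.31606, abs=1e-5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            haldane(-1.0)

    def test_monotone_in_distance(self):
        d = np.linspace(0, 200, 100)
        theta = haldane(d)
        assert (np.diff(theta) > 0).all()
        assert (theta <= 0.5).all()


class TestBuildDescent:
    def test_trio_all_zero_iv(self, trio):
        part = build_descent(trio, np.zeros(2, np.uint8))
        assert part.founder_gene("C1", 0) == ("F1", 0)
        assert part.founder_gene("C1", 1) == ("M1", 0)

    def test_all_zero_iv_only_paternal_line_genes(self):
        ped = fig1_like_pedigree()
        part = build_descent(ped, np.zeros(ped.n_meioses, np.uint8))
        # every inherited slot points at the parent's own paternal copy
        for ind in ped.individuals:
            if not ind.is_founder:
                i = ped.index[ind.id]
                s = ped.index[ind.sire]
                assert part.labels[2 * i] == part.labels[2 * s]

    def test_random_ivs_match_path_tracing_oracle(self):
        ped = fig1_like_pedigree()
        rng = np.random.default_rng(0)
        for _ in range(20):
            iv = rng.integers(0, 2, ped.n_meioses).astype(np.uint8)
            assert (build_descent(ped, iv).labels == oracle_labels(ped, iv)).all()

    def test_length_mismatch(self, trio):
        with pytest.raises(ValueError):
            build_descent(trio, np.zeros(3, np.uint8))


class TestLocusLikelihood:
    def test_no_observations(self, trio):
        part = build_descent(trio, np.zeros(2, np.uint8))
        assert locus_likelihood(part, {}, 0.3) == 1.0

    def test_single_hom_alt_two_distinct_genes(self, trio):
        part = build_descent(trio, np.zeros(2, np.uint8))
        assert locus_likelihood(part, {"F1": 2}, 0.3) == pytest.approx(0.09)

    def test_shared_gene_contradiction(self, trio):
        part = build_descent(trio, np.zeros(2, np.uint8))
        # child shares father's paternal gene: 0 vs 2 copies is impossible
        assert locus_likelihood(part, {"F1": 0, "C1": 2}, 0.3) == 0.0

    @pytest.mark.parametrize("ped_idx", range(5))
    def test_matches_brute_force_enumeration(self, ped_idx):
        ped = small_pedigree_battery()[ped_idx]
        rng = np.random.default_rng(ped_idx)
        markers = [Marker("chr1", 1000, "A", "C", float(p))
                   for p in rng.uniform(0.1, 0.9, 1)]
        for rep in range(10):
            iv = rng.integers(0, 2, ped.n_meioses).astype(np.uint8)
            g = random_genotypes(ped, markers, rng, missing_rate=0.3)
            gt = {pid: int(g.geno[k, 0]) for k, pid in enumerate(g.ids)}
            part = build_descent(ped, iv)
            got = locus_likelihood(part, gt, markers[0].alt_freq)
            want = oracle_locus_likelihood(
                ped, part.labels, gt, markers[0].alt_freq
            )
            assert got == pytest.approx(want, rel=1e-12)


class TestTransitionProb:
    def test_identity_at_zero_theta(self):
        iv = np.array([0, 1, 0])
        assert transition_prob(iv, iv, 0.0) == 1.0

    def test_single_flip(self):
        assert transition_prob(
            np.array([0, 0]), np.array([1, 0]), 0.1
        ) == pytest.approx(0.09)

    def test_normalization(self):
        m = 3
        iv_a = np.array([0, 1, 0])
        total = sum(
            transition_prob(iv_a, np.array([(s >> j) & 1 for j in range(m)]), 0.23)
            for s in range(2**m)
        )
        assert total == pytest.approx(1.0)


def _framework(ped, markers, geno):
    return GenotypeMatrix(ped.ids, markers, np.asarray(geno, np.int8))


class TestExactPosterior:
    def test_uniform_when_unobserved(self, trio):
        markers = [Marker("chr1", 1000, "A", "C", 0.5)]
        fw = _framework(trio, markers, [[-1], [-1], [-1]])
        ivs = exact_iv_posterior(trio, fw, GMAP, seed=0, n_samples=10)
        assert np.allclose(ivs.marginals, 0.25)

    def test_homozygous_data_is_iv_symmetric(self, trio):
        markers = [Marker("chr1", 1000, "A", "C", 0.5)]
        fw = _framework(trio, markers, [[2], [0], [1]])
        ivs = exact_iv_posterior(trio, fw, GMAP, seed=0, n_samples=10)
        assert np.allclose(ivs.marginals, 0.25)

    def test_impossible_data_raises(self, trio):
        markers = [Marker("chr1", 1000, "A", "C", 0.5)]
        fw = _framework(trio, markers, [[0], [0], [2]])
        with pytest.raises(MendelianInconsistencyError):
            exact_iv_posterior(trio, fw, GMAP, seed=0)

    def test_m_max_guard(self):
        ped = fig1_like_pedigree()
        markers = [Marker("chr1", 1000, "A", "C", 0.5)]
        fw = _framework(ped, markers, -np.ones((16, 1)))
        with pytest.raises(ValueError, match="m_max"):
            exact_iv_posterior(ped, fw, GMAP, seed=0, m_max=16)

    @pytest.mark.parametrize("ped_idx", range(5))
    def test_matches_enumeration_oracle(self, ped_idx):
        ped = small_pedigree_battery()[ped_idx]
        rng = np.random.default_rng(100 + ped_idx)
        L = 3 if ped.n_meioses >= 6 else 4
        markers = [
            Marker("chr1", int(3e5 * (t + 1)), "A", "C",
                   float(rng.uniform(0.2, 0.8)))
            for t in range(L)
        ]
        g = random_genotypes(ped, markers, rng, missing_rate=0.25)
        ivs = exact_iv_posterior(ped, g, GMAP, seed=1, n_samples=10)
        want = oracle_iv_marginals(ped, g.geno, markers, GMAP)
        assert np.abs(ivs.marginals - want).max() < 1e-12

    def test_joint_samples_follow_marginals(self, quartet):
        rng = np.random.default_rng(5)
        markers = [Marker("chr1", 100_000, "A", "C", 0.4),
                   Marker("chr1", 2_000_000, "A", "C", 0.6)]
        g = random_genotypes(quartet, markers, rng, missing_rate=0.0)
        ivs = exact_iv_posterior(quartet, g, GMAP, seed=2, n_samples=8000)
        S = 2**quartet.n_meioses
        st = np.zeros(ivs.bits.shape[0], int)
        for j in range(quartet.n_meioses):
            st |= ivs.bits[:, j, 0].astype(int) << j
        emp = np.bincount(st, minlength=S) / len(st)
        tv = 0.5 * np.abs(emp - ivs.marginals[0]).sum()
        assert tv < 0.03


class TestMcmc:
    def test_same_seed_identical(self, quartet):
        rng = np.random.default_rng(6)
        markers = [Marker("chr1", 100_000, "A", "C", 0.4),
                   Marker("chr1", 2_000_000, "A", "C", 0.6)]
        g = random_genotypes(quartet, markers, rng, missing_rate=0.0)
        a = sample_iv_mcmc(quartet, g, GMAP, n_samples=50, burn_in=20, thin=1, seed=9)
        b = sample_iv_mcmc(quartet, g, GMAP, n_samples=50, burn_in=20, thin=1, seed=9)
        assert (a.bits == b.bits).all()

    def test_unobserved_data_uniform(self, trio):
        markers = [Marker("chr1", 1000, "A", "C", 0.5)]
        fw = _framework(trio, markers, [[-1], [-1], [-1]])
        mc = sample_iv_mcmc(trio, fw, GMAP, n_samples=4000, burn_in=100,
                            thin=2, seed=3)
        st = (mc.bits[:, 0, 0].astype(int)
              | (mc.bits[:, 1, 0].astype(int) << 1))
        counts = np.bincount(st, minlength=4)
        chi2 = stats.chisquare(counts).pvalue
        assert chi2 > 1e-4

    def test_marginals_close_to_exact_on_constrained_quartet(self, quartet):
        # opposite-homozygote siblings: the configuration that traps a pure
        # meiosis-wise sampler
        markers = [Marker("chr1", 100_000, "A", "C", 0.3),
                   Marker("chr1", 2_100_000, "A", "C", 0.4)]
        geno = [[1, 1], [1, 0], [2, 1], [0, 0]]
        fw = _framework(quartet, markers, geno)
        exact = exact_iv_posterior(quartet, fw, GMAP, seed=0, n_samples=10)
        mc = sample_iv_mcmc(quartet, fw, GMAP, n_samples=6000, burn_in=300,
                            thin=2, seed=4)
        S = 2**quartet.n_meioses
        for t in range(2):
            st = np.zeros(mc.bits.shape[0], int)
            for j in range(quartet.n_meioses):
                st |= mc.bits[:, j, t].astype(int) << j
            emp = np.bincount(st, minlength=S) / len(st)
            tv = 0.5 * np.abs(emp - exact.marginals[t]).sum()
            assert tv < 0.03

    def test_retained_samples_always_consistent(self, quartet):
        markers = [Marker("chr1", 100_000, "A", "C", 0.3),
                   Marker("chr1", 2_100_000, "A", "C", 0.4)]
        geno = [[1, 1], [1, 0], [2, 1], [0, 0]]
        fw = _framework(quartet, markers, geno)
        mc = sample_iv_mcmc(quartet, fw, GMAP, n_samples=300, burn_in=50,
                            thin=1, seed=8)
        for s in range(0, 300, 37):
            for t in range(2):
                part = build_descent(quartet, mc.bits[s, :, t])
                gt = {pid: geno[k][t] for k, pid in enumerate(quartet.ids)}
                assert locus_likelihood(part, gt, markers[t].alt_freq) > 0

    def test_impossible_data_raises(self, trio):
        markers = [Marker("chr1", 1000, "A", "C", 0.5)]
        fw = _framework(trio, markers, [[0], [0], [2]])
        with pytest.raises(MendelianInconsistencyError):
            sample_iv_mcmc(trio, fw, GMAP, n_samples=10, burn_in=5, seed=0)
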