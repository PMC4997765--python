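import numpy as np
import pandas as pd
import pytest

from pedimpute.evaluate import (
    ScenarioConfig,
    allele_accuracy,
    fraction_imputed,
    genotype_concordance,
    mask_nonframework,
    run_strategy_comparison,
    simulate_scenario,
    stratify_by_freq,
)
from pedimpute.impute import STRICT, ImputationResult
from pedimpute.pedio import GenotypeMatrix, Marker


def _markers(n, p=0.5, start=1000, step=1000):
    return [Marker("chr1", start + step * k, "A", "C", p) for k in range(n)]


def _result(markers, targets, thr_n, thr_dose, thr_allele, ml_dose=None):
    Ld, nt = np.asarray(thr_n).shape
    gt_post = np.full((Ld, nt, 3), 1 / 3)
    slot_post = np.full((Ld, nt, 2), 0.5)
    return ImputationResult(
        markers=markers,
        target_ids=targets,
        donor_ids=[],
        gt_post=gt_post,
        slot_post=slot_post,
        ml_dose=np.asarray(
            ml_dose if ml_dose is not None else np.zeros((Ld, nt)), np.int8
        ),
        thr_n=np.asarray(thr_n, np.int8),
        thr_dose=np.asarray(thr_dose, np.int8),
        thr_allele=np.asarray(thr_allele, np.int8),
        site_ok=np.ones(Ld, bool),
        thresholds=STRICT,
    )


class TestMaskNonframework:
    def test_mixed_matrix_counts(self):
        markers = _markers(10)
        geno = np.ones((3, 10), np.int8)
        g = GenotypeMatrix(["a", "b", "c"], markers, geno)
        framework = markers[::2]
        masked, truth = mask_nonframework(g, framework)
        assert (masked.geno == -1).sum() == 3 * 5
        assert truth.n_markers == 5
        assert (truth.geno == 1).all()

    def test_framework_only_identity(self):
        markers = _markers(4)
        g = GenotypeMatrix(["a"], markers, np.ones((1, 4), np.int8))
        masked, truth = mask_nonframework(g, markers)
        assert (masked.geno == g.geno).all()
        assert truth.n_markers == 0

    def test_all_dense_fully_masked(self):
        markers = _markers(4)
        g = GenotypeMatrix(["a"], markers, np.ones((1, 4), np.int8))
        masked, truth = mask_nonframework(g, [])
        assert (masked.geno == -1).all()
        assert truth.n_markers == 4


class TestAlleleAccuracy:
    def test_counting(self):
        markers = _markers(10)
        truth = GenotypeMatrix(["x"], markers, np.ones((1, 10), np.int8))
        # 10 markers: 5 full calls RA (correct), 4 single-allele alt calls
        # (all in truth), 1 full call AA vs truth RA -> 1 of 2 correct
        thr_n = [[2]] * 5 + [[1]] * 4 + [[2]]
        thr_dose = [[1]] * 5 + [[-1]] * 4 + [[2]]
        thr_allele = [[-1]] * 5 + [[1]] * 4 + [[-1]]
        res = _result(markers, ["x"], thr_n, thr_dose, thr_allele)
        rep = allele_accuracy(res, truth, "threshold")
        row = rep.table.iloc[0]
        assert row.attempted == 16
        assert row.correct == 15
        assert row.accuracy == pytest.approx(15 / 16)
        assert row.frac_markers == pytest.approx(1.0)
        assert row.frac_alleles == pytest.approx(16 / 20)
        assert row.frac_genotypes == pytest.approx(6 / 10)

    def test_single_alt_vs_het_truth_is_correct(self):
        markers = _markers(1)
        truth = GenotypeMatrix(["x"], markers, np.array([[1]], np.int8))
        res = _result(markers, ["x"], [[1]], [[-1]], [[1]])
        rep = allele_accuracy(res, truth, "threshold")
        assert rep.table.iloc[0].correct == 1

    def test_ra_call_vs_aa_truth_one_of_two(self):
        markers = _markers(1)
        truth = GenotypeMatrix(["x"], markers, np.array([[2]], np.int8))
        res = _result(markers, ["x"], [[2]], [[1]], [[-1]])
        row = allele_accuracy(res, truth, "threshold").table.iloc[0]
        assert (row.attempted, row.correct) == (2, 1)

    def test_missing_truth_not_attempted(self):
        markers = _markers(2)
        truth = GenotypeMatrix(["x"], markers, np.array([[1, -1]], np.int8))
        res = _result(markers, ["x"], [[2], [2]], [[1], [1]], [[-1], [-1]])
        row = allele_accuracy(res, truth, "threshold").table.iloc[0]
        assert row.attempted == 2


class TestFractionImputed:
    def test_most_likely_always_full(self):
        markers = _markers(5)
        res = _result(markers, ["x"], [[0]] * 5, [[-1]] * 5, [[-1]] * 5)
        marker_level, allele_level = fraction_imputed(res, "most_likely")
        assert marker_level == 1.0 and allele_level == 1.0

    def test_no_calls(self):
        markers = _markers(5)
        res = _result(markers, ["x"], [[0]] * 5, [[-1]] * 5, [[-1]] * 5)
        marker_level, allele_level = fraction_imputed(res, "threshold")
        assert marker_level == 0.0 and allele_level == 0.0

    def test_counting_oracle(self):
        markers = _markers(4)
        thr_n = [[2], [1], [0], [1]]
        res = _result(markers, ["x"], thr_n, [[1], [-1], [-1], [-1]],
                      [[-1], [0], [-1], [1]])
        marker_level, allele_level = fraction_imputed(res, "threshold")
        assert marker_level == pytest.approx(3 / 4)
        assert allele_level == pytest.approx(4 / 8)


class TestStratifyByFreq:
    def test_single_occupied_bin(self):
        markers = _markers(5, p=0.9)
        truth = GenotypeMatrix(["x"], markers, np.full((1, 5), 2, np.int8))
        res = _result(markers, ["x"], [[2]] * 5, [[2]] * 5, [[-1]] * 5)
        out = stratify_by_freq(res, truth, "threshold")
        occupied = out[out.n_alleles > 0]
        assert list(occupied.bin) == ["[0.75, 1.0)"]
        assert occupied.iloc[0].imputation_rate == pytest.approx(1.0)

    def test_histogram_totals(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(0.05, 0.95, 40)
        markers = [Marker("chr1", 1000 * (k + 1), "A", "C", float(p))
                   for k, p in enumerate(ps)]
        doses = rng.integers(0, 3, size=(1, 40)).astype(np.int8)
        truth = GenotypeMatrix(["x"], markers, doses)
        res = _result(markers, ["x"], [[0]] * 40, [[-1]] * 40, [[-1]] * 40)
        out = stratify_by_freq(res, truth, "threshold")
        assert out.n_alleles.sum() == 80

    def test_rare_row_present(self):
        markers = _markers(3, p=0.1)
        truth = GenotypeMatrix(["x"], markers, np.array([[1, 1, 0]], np.int8))
        res = _result(markers, ["x"], [[2]] * 3, [[1], [1], [0]], [[-1]] * 3)
        out = stratify_by_freq(
            res, truth, "threshold", rare_alt=np.array([True, False, False])
        )
        rare = out[out.bin == "rare"].iloc[0]
        assert rare.n_alleles == 1
        assert rare.imputation_rate == pytest.approx(1.0)


class TestConcordance:
    def test_identical(self):
        markers = _markers(5)
        g = GenotypeMatrix(["a", "b"], markers,
                           np.ones((2, 5), np.int8))
        assert genotype_concordance(g, g)["concordance"] == 1.0

    def test_one_in_hundred(self):
        markers = _markers(50)
        a = GenotypeMatrix(["a", "b"], markers, np.ones((2, 50), np.int8))
        b = a.copy()
        b.geno[0, 0] = 2
        assert genotype_concordance(a, b)["concordance"] == pytest.approx(0.99)

    def test_no_overlap_rejected(self):
        markers = _markers(2)
        a = GenotypeMatrix(["a"], markers, np.full((1, 2), -1, np.int8))
        with pytest.raises(ValueError):
            genotype_concordance(a, a)

    def test_simulated_depth_comparison(self):
        from pedimpute.simdata import (
            CoverageModel, fig1_like_pedigree, make_markers,
            simulate_observation, simulate_truth,
        )
        from pedimpute.pedio import GeneticMap

        ped = fig1_like_pedigree()
        rng = np.random.default_rng(5)
        markers = make_markers(300, 5000, rng)
        truth = simulate_truth(ped, markers, GeneticMap.constant_rate(), seed=5)
        deep = simulate_observation(truth, CoverageModel(30, 0.005), seed=1)
        shallow = simulate_observation(truth, CoverageModel(12, 0.005), seed=2)
        out = genotype_concordance(deep, shallow)
        both = (deep.geno >= 0) & (shallow.geno >= 0)
        assert out["n_both"] == int(both.sum())
        assert out["concordance"] == pytest.approx(
            (deep.geno[both] == shallow.geno[both]).mean()
        )
        assert out["n_callable_a"] > out["n_callable_b"]


class TestScenario:
    def test_strategy_comparison_deterministic(self):
        cfg = ScenarioConfig(
            n_framework=25, n_dense=80, n_iv_samples=60, burn_in=40,
        )
        a = run_strategy_comparison(cfg, seed=5)
        b = run_strategy_comparison(cfg, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert set(a.strategy) == {"gigi-pick", "founders", "bottom"}

    def test_scenario_shapes_and_ascertainment(self):
        cfg = ScenarioConfig(n_framework=30, n_dense=100)
        scen = simulate_scenario(cfg, seed=2)
        assert len(scen.framework_idx) == 30
        assert len(scen.dense_idx) <= 100
        # every dense site is variable among the WGS-designated members
        from pedimpute.simdata import WGS_IDS

        rows = [scen.pedigree.index[i] for i in WGS_IDS]
        g = scen.truth.genotypes().geno
        assert (g[rows][:, scen.dense_idx].sum(axis=0) > 0).all()
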