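import numpy as np
import pytest

from rsplis import (
    GenotypeStudySpec,
    build_synthetic_pool,
    make_scenario,
    run_genotype_study,
    simulate_scenario,
)
from rsplis.simstudy import calibrate_beta0, score_changepoints


class TestMakeScenario:
    def test_five_region_design_region1(self):
        scen = make_scenario(1, L0=600)
        r1 = scen.chromosomes[0][0]
        model = r1.model()
        np.testing.assert_allclose(model.pi, [0.91, 0.09], atol=0.001)
        np.testing.assert_allclose(r1.f1.xi, [0.1, 0.9])
        np.testing.assert_allclose(r1.f1.mu, [1.0, 3.0])
        assert scen.true_changepoints().tolist() == [600, 1200, 1800, 2400]
        assert scen.m_true == 2

    def test_case1_zero_perturbation_keeps_base_transitions(self):
        scen = make_scenario(4, upsilon1=0.0, mu_base=1.0)
        c1r2 = scen.chromosomes[0][1]
        assert c1r2.a10 == pytest.approx(0.03)
        assert c1r2.f1.mu[0] == pytest.approx(2.5)  # mu11 + 1.5

    def test_case2_mean_chaining(self):
        scen = make_scenario(5, upsilon2=2.0, mu_base=0.5)
        # mu21(2) = mu11(1) + 0.5 + upsilon2 = 3.0
        assert scen.chromosomes[1][1].f1.mu[0] == pytest.approx(3.0)

    def test_out_of_range_settings_rejected(self):
        with pytest.raises(ValueError):
            make_scenario(4, upsilon1=0.9)
        with pytest.raises(ValueError):
            make_scenario("bogus")

    def test_simulation_reproducible_and_aligned(self):
        scen = make_scenario(4, upsilon1=0.15)
        a = simulate_scenario(scen, 5)
        b = simulate_scenario(scen, 5)
        assert len(a) == 2 and all(len(z) == 4000 for z in a)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.z, y.z)

    def test_stationary_frequencies_match_design(self):
        scen = make_scenario(1, L0=1200)
        z = simulate_scenario(scen, 77)[0]
        # region 2 has stationary pi1 = 0.02/0.97 ~ 0.0206
        r2 = z.theta_truth[1200:2400]
        pi1 = 0.02 / 0.97
        se = np.sqrt(pi1 * (1 - pi1) / 1200)
        assert abs(r2.mean() - pi1) < 6 * se


class TestFdrStudySmoke:
    def test_case2_fdp_bounded_and_reproducible(self):
        from rsplis import AnalysisConfig
        from rsplis.simstudy import run_fdr_study

        scen = make_scenario(5, upsilon2=1.0, mu_base=1.0)
        cfg = AnalysisConfig(K_max=4, m_max=3, h=2)
        res = run_fdr_study(scen, alpha=0.1, reps=3, seed=52, config=cfg)
        for meth in ("rsplis", "plis"):
            # loose single-digit-replication bound around the nominal level
            assert res[meth]["fdr"] <= 0.25
            assert 0 <= res[meth]["sensitivity"] <= 1
        res2 = run_fdr_study(scen, alpha=0.1, reps=3, seed=52, config=cfg)
        assert res2["rsplis"]["fdr"] == res["rsplis"]["fdr"]


class TestScorer:
    def test_exact_recovery_scores_one(self):
        cands = np.arange(300, 2701, 300)
        truth = np.array([600, 1200, 1800, 2400])
        assert score_changepoints(truth, truth, cands) == (1.0, 1.0)

    @pytest.mark.parametrize(
        "w_hat,expected",
        [
            ([600, 900], (0.25, 0.8)),       # 1 of 4 true; 1 of 5 false kept
            ([], (0.0, 1.0)),
            ([300, 900, 1500, 2100, 2700], (0.0, 0.0)),
        ],
    )
    def test_set_arithmetic_cases(self, w_hat, expected):
        cands = np.arange(300, 2701, 300)
        truth = np.array([600, 1200, 1800, 2400])
        sens, spec = score_changepoints(np.array(w_hat, int), truth, cands)
        assert (sens, spec) == pytest.approx(expected)


class TestSyntheticPool:
    def test_perfect_copy_gives_monomorphic_blocks(self):
        pool = build_synthetic_pool(40, 200, block_length=20, copy_prob=1.0, seed=1)
        h = pool.haplotypes
        for s in range(0, 200, 20):
            block = h[:, s : s + 20]
            assert np.all(block == block[:, :1])

    def test_zero_copy_gives_uncorrelated_neighbors(self):
        pool = build_synthetic_pool(4000, 400, block_length=50, copy_prob=0.0, seed=2)
        h = pool.haplotypes.astype(float)
        cors = [np.corrcoef(h[:, j], h[:, j + 1])[0, 1] for j in range(0, 399, 7)]
        assert abs(np.mean(cors)) < 0.02

    def test_markov_autocorrelation_matches_closed_form(self):
        # With a shared allele frequency p, copying with prob c gives
        # corr(X_l, X_{l+1}) = c  (two-state Markov chain autocorrelation)
        c = 0.95
        pool = build_synthetic_pool(
            6000, 300, block_length=300, copy_prob=c, maf_range=(0.3, 0.3001), seed=3
        )
        h = pool.haplotypes.astype(float)
        cors = [np.corrcoef(h[:, j], h[:, j + 1])[0, 1] for j in range(1, 299, 5)]
        assert np.mean(cors) == pytest.approx(c, abs=0.02)

    def test_reproducible(self):
        a = build_synthetic_pool(10, 50, seed=9).haplotypes
        b = build_synthetic_pool(10, 50, seed=9).haplotypes
        np.testing.assert_array_equal(a, b)


class TestGenotypeStudy:
    def test_relevant_set_has_39_snps(self):
        spec = GenotypeStudySpec()
        rel = spec.relevant_flat()
        assert len(rel) == 39
        causal = set(spec.causal_flat().tolist())
        assert not (set(rel.tolist()) & causal)

    def test_beta0_calibration_hits_target_rate(self):
        spec = GenotypeStudySpec(chrom_lengths=(600, 600),
                                 causal=((100, 200, 300, 400), (50, 54, 58, 62)))
        pool = build_synthetic_pool(120, 1200, seed=4)
        b0 = calibrate_beta0(pool, spec, n_mc=40000, seed=5)
        # independent MC check of the solved prevalence
        rng = np.random.default_rng(99)
        idx = rng.integers(0, pool.n_haplotypes, size=(40000, 2))
        x = (pool.haplotypes[idx[:, 0]] + pool.haplotypes[idx[:, 1]])[
            :, spec.causal_flat()
        ]
        from scipy.special import expit

        rate = expit(b0 + np.log(1.5) * x.sum(axis=1)).mean()
        assert rate == pytest.approx(0.03, abs=0.005)

    def test_small_study_runs_end_to_end(self):
        from rsplis import AnalysisConfig

        spec = GenotypeStudySpec(
            chrom_lengths=(700, 700),
            causal=((100, 250, 400, 550), (600, 604, 608, 612)),
            n_cases=60, n_controls=60,
        )
        pool = build_synthetic_pool(120, 1400, seed=6)
        cfg = AnalysisConfig(K_max=1, m_max=1, refit_restarts=1, segment_restarts=1)
        res = run_genotype_study(
            pool, spec, reps=1, seed=7, config=cfg, M_grid=np.array([20, 100, 400])
        )
        for meth in ("rsplis", "plis"):
            curve = res[meth]
            assert np.all((0 <= curve) & (curve <= 1))
            assert np.all(np.diff(curve) >= 0)  # top-M sensitivity is monotone
        assert res["n_relevant"] == 39
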