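"""Gibbs samplers for the linear and threshold animal models.

Validation strategy: closed-form identities (ridge shrinkage), a dense
mixed-model-equation oracle for the sampler at fixed variances, the
truncated-normal building block against scipy, and small-scale
parameter-recovery / coverage smoke tests on simulated truth.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

import liabel as lb
from liabel._gibbs import sample_truncated_normal
from liabel.diagnostics import batch_means_se


def identity_design(y, n_cg=1):
    """One record per animal, identity H^-1, single CG."""
    n = len(y)
    hinv = lb.RelationshipMatrix(pd.Index(range(1, n + 1)), np.eye(n), "Hinv")
    phen = pd.DataFrame({"animal": range(1, n + 1), "cg": ["c0"] * n, "y": y})
    return lb.build_design(phen, hinv)


class TestModelSpec:
    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError):
            lb.ModelSpec(n_iterations=100, burn_in=100)

    def test_thin_positive(self):
        with pytest.raises(ValueError):
            lb.ModelSpec(thin=0)

    def test_retained_draw_count(self, small_qc_phenotypes, small_population):
        A = lb.build_A(small_population.pedigree)
        hinv = lb.h_inverse_single_step(A, None)
        design = lb.build_design(small_qc_phenotypes, hinv)
        spec = lb.ModelSpec(model_type="linear", n_iterations=2_000, burn_in=500,
                            thin=25, seed=1)
        chain = lb.run_gibbs(design, spec)
        assert chain.n_kept == (2_000 - 500) // 25
        assert (chain.sigma2_a > 0).all()


class TestSolveMME:
    def test_ridge_shrinkage_identity(self):
        # Z = I, X = intercept, H^-1 = I: BLUP shrinks centred records by
        # sigma2_a / (sigma2_a + sigma2_e) exactly
        rng = np.random.default_rng(0)
        y = (rng.random(12) < 0.4).astype(float)
        design = identity_design(y)
        s2a, s2e = 0.3, 0.7
        beta, a_hat = lb.solve_mme(design, s2a, s2e)
        shrink = s2a / (s2a + s2e)
        centred = y - y.mean()
        assert np.allclose(a_hat.to_numpy(), shrink * centred, atol=1e-6)

    def test_vanishing_genetic_variance_kills_blup(self):
        rng = np.random.default_rng(1)
        design = identity_design((rng.random(10) < 0.5).astype(float))
        _, a_hat = lb.solve_mme(design, 1e-10, 1.0)
        assert np.abs(a_hat.to_numpy()).max() < 1e-8

    def test_positive_variances_required(self):
        design = identity_design(np.array([0.0, 1.0, 0.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            lb.solve_mme(design, 0.0, 1.0)


class TestTruncatedNormal:
    @pytest.mark.parametrize(
        "mu, lower_tail, bound",
        [(0.0, False, 0.0), (-1.5, False, 0.0), (0.8, True, 0.0), (-5.5, False, 0.0)],
    )
    def test_moments_and_support(self, mu, lower_tail, bound):
        np.random.seed(11)
        draws = np.array(
            [sample_truncated_normal(mu, 1.0, bound, lower_tail) for _ in range(60_000)]
        )
        if lower_tail:
            assert (draws <= bound).all()
            expected = truncnorm.mean(-np.inf, bound - mu, loc=mu)
        else:
            assert (draws >= bound).all()
            expected = truncnorm.mean(bound - mu, np.inf, loc=mu)
        assert draws.mean() == pytest.approx(expected, abs=0.02)


class TestGibbsAgainstOracles:
    def test_ridge_exchange_closed_form(self):
        """Fixed-variance Gibbs with identity H^-1 reproduces the ridge
        posterior mean within Monte-Carlo error."""
        rng = np.random.default_rng(2)
        y = (rng.random(30) < 0.4).astype(float)
        design = identity_design(y)
        spec = lb.ModelSpec(model_type="linear", n_iterations=30_000, burn_in=3_000,
                            thin=5, seed=7, fix_variances=True,
                            sigma2_a_init=0.3, sigma2_e_init=0.7)
        chain = lb.run_gibbs(design, spec)
        _, a_hat = lb.solve_mme(design, 0.3, 0.7)
        post = chain.a.mean(axis=0)
        se = np.array([batch_means_se(chain.a[:, i]) for i in range(30)])
        assert (np.abs(post - a_hat.to_numpy()) <= 3 * se).all()

    def test_no_signal_threshold_gebvs_near_zero(self):
        rng = np.random.default_rng(3)
        y = (rng.random(60) < 0.5).astype(float)  # pure noise at alpha = 0.5
        design = identity_design(y)
        spec = lb.ModelSpec(model_type="threshold", n_iterations=10_000, burn_in=2_000,
                            thin=5, seed=9, fix_variances=True, sigma2_a_init=0.05)
        chain = lb.run_gibbs(design, spec)
        post = chain.a.mean(axis=0)
        se = np.array([batch_means_se(chain.a[:, i]) for i in range(60)])
        assert (np.abs(post) <= 4 * se + 0.05).all()

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(4)
        y = (rng.random(20) < 0.3).astype(float)
        design = identity_design(y)
        spec = lb.ModelSpec(model_type="threshold", n_iterations=1_000, burn_in=200,
                            thin=5, seed=21)
        c1, c2 = lb.run_gibbs(design, spec), lb.run_gibbs(design, spec)
        assert np.array_equal(c1.sigma2_a, c2.sigma2_a)
        assert np.array_equal(c1.a, c2.a)

    def test_degenerate_response_rejected(self):
        with pytest.raises(ValueError, match="variability"):
            identity_design(np.ones(10))


class TestSummarize:
    def test_constant_chain_summary(self):
        chain = lb.MCMCChain(
            sigma2_a=np.full(200, 0.4), sigma2_e=np.full(200, 0.4),
            a=np.zeros((200, 3)), animal_ids=pd.Index([1, 2, 3]),
            model_type="linear", spec=lb.ModelSpec(model_type="linear"),
        )
        s = lb.summarize(chain)
        assert s.h2 == pytest.approx(0.5)
        assert s.h2_hpd == (0.5, 0.5)
        assert s.sigma2_a_hpd == (0.4, 0.4)

    def test_hpd_width_on_uniform_grid(self):
        chain = lb.MCMCChain(
            sigma2_a=np.arange(1.0, 101.0), sigma2_e=np.ones(100),
            a=np.zeros((100, 2)), animal_ids=pd.Index([1, 2]),
            model_type="threshold", spec=lb.ModelSpec(),
        )
        s = lb.summarize(chain)
        lo, hi = s.sigma2_a_hpd
        assert hi - lo == 94.0

    def test_few_draws_warns(self):
        chain = lb.MCMCChain(
            sigma2_a=np.full(10, 0.3), sigma2_e=np.full(10, 0.7),
            a=np.zeros((10, 2)), animal_ids=pd.Index([1, 2]),
            model_type="linear", spec=lb.ModelSpec(model_type="linear"),
        )
        with pytest.warns(UserWarning, match="retained"):
            s = lb.summarize(chain)
        assert s.warnings


class TestRecoverySmoke:
    """Scaled-down parameter recovery and HPD coverage across seeds."""

    @staticmethod
    def _fit_h2(seed):
        cfg = lb.SimConfig(
            n_founders=120, n_generations=2, offspring_per_mating=10,
            n_snps=400, h2_liability=0.35, prevalence=0.10, n_cgs=4,
            prop_genotyped=0.3, seed=seed,
        )
        pop = lb.simulate_population(cfg)  # 120 + 600 animals
        phen, _ = lb.filter_cgs(pop.phenotypes)
        phen, _ = lb.check_connectedness(phen, pop.pedigree)
        A = lb.build_A(pop.pedigree)
        G = lb.build_G(pop.genotypes)
        hinv = lb.h_inverse_single_step(A, G)
        design = lb.build_design(phen, hinv)
        spec = lb.ModelSpec(model_type="threshold", n_iterations=12_000,
                            burn_in=3_000, thin=15, seed=seed + 100)
        return lb.summarize(lb.run_gibbs(design, spec))

    def test_hpd_coverage_across_seeds(self):
        """95% HPD for liability heritability covers the simulation truth in
        a clear majority of replicate populations (smoke test, not a
        calibration proof)."""
        hits = 0
        for seed in (1, 2, 3, 4, 5):
            s = self._fit_h2(seed)
            lo, hi = s.h2_hpd
            hits += lo <= 0.35 <= hi
        assert hits >= 3
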