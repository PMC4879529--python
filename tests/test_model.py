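"""REML estimation: likelihood correctness, optimizer quality, heritability,
the unbiased variance decomposition, and the multi-GRM model."""

import numpy as np
import pytest

import pcgreml as pg
from pcgreml.genotype import GRM, compute_grm, standardize
from pcgreml.model import GREML, GREMLResults

from conftest import dense_restricted_loglik


def random_instance(n=12, p=3, m=30, seed=0):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, m))
    K = Z @ Z.T / m
    y = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    return y, X, GRM(K=K, m_snps=m)


class TestRestrictedLoglik:
    def test_identity_grm_depends_on_sum_only(self):
        """With K = I only tau + sigma2 is identifiable: the likelihood is
        constant along that line."""
        rng = np.random.default_rng(1)
        n = 15
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        grm = GRM(K=np.eye(n), m_snps=1)
        vals = [
            pg.restricted_loglik(y, X, grm, tau, 1.0 - tau)
            for tau in (0.0, 0.3, 0.7, 1.0)
        ]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-10)

    @pytest.mark.parametrize("tau,sigma2", [(0.7, 0.5), (0.0, 1.2), (2.0, 0.1)])
    def test_matches_dense_oracle(self, tau, sigma2):
        y, X, grm = random_instance(seed=5)
        ours = pg.restricted_loglik(y, X, grm, tau, sigma2)
        oracle = dense_restricted_loglik(y, X, grm.K, tau, sigma2)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_duplicated_covariate_rejected(self):
        y, X, grm = random_instance()
        Xdup = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            pg.restricted_loglik(y, Xdup, grm, 0.5, 0.5)

    def test_both_components_zero_rejected(self):
        y, X, grm = random_instance()
        with pytest.raises(ValueError):
            pg.restricted_loglik(y, X, grm, 0.0, 0.0)


class TestFitSingle:
    def test_optimum_beats_dense_grid_oracle(self):
        """Profile optimum vs a brute-force grid over the heritability ratio
        (dense-matrix likelihood): the optimizer is never worse than the grid
        by more than 1e-6, and its own likelihood value agrees with the
        dense oracle at the optimum."""
        cfg = pg.PopulationConfig(
            n_individuals=30, n_snps=500, n_subpops=2, fst=0.05, seed=33,
        )
        panel = pg.simulate_structured_genotypes(cfg)
        Z = standardize(panel)
        grm = compute_grm(Z)
        truth = pg.simulate_phenotype_lmm(
            panel, np.zeros((30, 0)), [], tau=0.4, sigma2=0.4, seed=1, Z=Z.Z
        )
        X = np.ones((30, 1))
        fit = pg.fit_reml_single(truth.y, X, grm)
        n, p = 30, 1
        best_grid = -np.inf
        for gamma in np.arange(0.0, 1.0, 0.001):
            # profile the scale s at this ratio with the dense oracle
            W = gamma * grm.K + (1 - gamma) * np.eye(n)
            Wi = np.linalg.inv(W)
            P = Wi - Wi @ X @ np.linalg.inv(X.T @ Wi @ X) @ X.T @ Wi
            s = (truth.y @ P @ truth.y) / (n - p)
            ll = dense_restricted_loglik(truth.y, X, grm.K, gamma * s, (1 - gamma) * s)
            best_grid = max(best_grid, ll)
        assert fit.llf_restricted >= best_grid - 1e-6
        dense_at_opt = dense_restricted_loglik(truth.y, X, grm.K, fit.tau, fit.sigma2)
        assert fit.llf_restricted == pytest.approx(dense_at_opt, abs=1e-8)

    def test_grid_oracle_on_small_instances(self):
        """Same dual check on a handful of random n <= 50 instances."""
        for seed in range(4):
            y, X, grm = random_instance(n=40, p=2, m=100, seed=seed)
            fit = pg.fit_reml_single(y, X, grm)
            n, p = X.shape
            best = -np.inf
            for gamma in np.linspace(0, 0.999, 200):
                W = gamma * grm.K + (1 - gamma) * np.eye(n)
                Wi = np.linalg.inv(W)
                P = Wi - Wi @ X @ np.linalg.inv(X.T @ Wi @ X) @ X.T @ Wi
                s = (y @ P @ y) / (n - p)
                best = max(
                    best,
                    dense_restricted_loglik(y, X, grm.K, gamma * s, (1 - gamma) * s),
                )
            assert fit.llf_restricted >= best - 1e-6

    def test_exact_fit_flagged_degenerate(self):
        y, X, grm = random_instance(n=20, p=3, seed=2)
        y_exact = X @ np.array([1.0, 2.0, -1.0])
        fit = pg.fit_reml_single(y_exact, X, grm)
        assert fit.degenerate and fit.tau == 0.0 and fit.sigma2 == 0.0

    def test_zero_variance_phenotype_rejected(self):
        y, X, grm = random_instance()
        with pytest.raises(ValueError, match="variance"):
            GREML(np.ones_like(y), X, grm)

    def test_duplicate_pc_triggers_rank_guard(self, two_pop_assets):
        _, grm, pcs, _ = two_pop_assets
        X = np.column_stack([np.ones(grm.n), pcs[:, :3], pcs[:, 2]])
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="rank"):
            GREML(rng.standard_normal(grm.n), X, grm)

    def test_scale_equivariance(self, two_pop_panel, two_pop_assets):
        """Rescaling y by c scales tau and sigma2 by c^2; h2 is unchanged."""
        Z, grm, pcs, _ = two_pop_assets
        truth = pg.simulate_phenotype_lmm(
            two_pop_panel, pcs, [0.02] * 10, 0.4, 0.4, seed=9, Z=Z.Z
        )
        X = np.column_stack([np.ones(200), pcs])
        f1 = pg.fit_reml_single(truth.y, X, grm)
        f2 = pg.fit_reml_single(3.0 * truth.y, X, grm)
        assert f2.tau == pytest.approx(9 * f1.tau, rel=1e-5)
        assert f2.sigma2 == pytest.approx(9 * f1.sigma2, rel=1e-5)
        assert f2.h2 == pytest.approx(f1.h2, abs=1e-6)

    def test_fit_dominates_truth_likelihood(self, mid_panel_assets):
        """The restricted likelihood at the optimum is >= its value at the
        generating parameters on (nearly) every replicate."""
        panel, Z, grm, pcs = mid_panel_assets
        X = np.column_stack([np.ones(300), pcs])
        wins = 0
        reps = 40
        for rep in range(reps):
            truth = pg.simulate_phenotype_lmm(
                panel, pcs, [0.02] * 10, 0.4, 0.4,
                seed=np.random.default_rng([21, rep]), Z=Z.Z,
            )
            fit = pg.fit_reml_single(truth.y, X, grm)
            ll_truth = pg.restricted_loglik(truth.y, X, grm, 0.4, 0.4)
            wins += fit.llf_restricted >= ll_truth - 1e-9
        assert wins / reps >= 0.95

    def test_mean_h2_recovers_half(self, mid_panel_assets):
        """Simulation design with ten causal PCs adjusted for: mean
        heritability estimate ~ 0.5 over 30 replicates."""
        panel, Z, grm, pcs = mid_panel_assets
        X = np.column_stack([np.ones(300), pcs])
        h2s = []
        for rep in range(30):
            truth = pg.simulate_phenotype_lmm(
                panel, pcs, [0.02] * 10, 0.4, 0.4,
                seed=np.random.default_rng([22, rep]), Z=Z.Z,
            )
            h2s.append(pg.fit_reml_single(truth.y, X, grm).h2)
        h2s = np.asarray(h2s)
        se = h2s.std(ddof=1) / np.sqrt(len(h2s))
        assert abs(h2s.mean() - 0.5) < 2 * se


class TestHeritability:
    @staticmethod
    def results_with(tau, sigma2, vc_cov=np.eye(2) * 1e-4):
        return GREMLResults(
            model=None, variance_components=np.array([tau, sigma2]),
            beta=np.zeros(1), beta_cov=np.zeros((1, 1)), vc_cov=vc_cov,
            llf_restricted=0.0, converged=True, boundary=tau == 0,
            n_used=100, p_fixed=1,
        )

    def test_boundary_and_equal_components(self):
        assert pg.heritability_with_se(self.results_with(0.0, 1.0))[0] == 0.0
        assert pg.heritability_with_se(self.results_with(0.4, 0.4))[0] == 0.5

    def test_zero_total_variance_raises(self):
        with pytest.raises(ZeroDivisionError):
            pg.heritability_with_se(self.results_with(0.0, 0.0))

    def test_delta_se_calibrated_against_monte_carlo(self, mid_panel_assets):
        """Delta-method SE within 20% of the empirical SD of h2-hat over
        200 simulated replicates."""
        panel, Z, grm, pcs = mid_panel_assets
        X = np.column_stack([np.ones(300), pcs])
        h2s, ses = [], []
        for rep in range(200):
            truth = pg.simulate_phenotype_lmm(
                panel, pcs, [0.02] * 10, 0.4, 0.4,
                seed=np.random.default_rng([5, rep]), Z=Z.Z,
            )
            h2, se = pg.heritability_with_se(pg.fit_reml_single(truth.y, X, grm))
            h2s.append(h2)
            ses.append(se)
        assert abs(np.mean(ses) / np.std(h2s) - 1) < 0.20


class TestDecomposition:
    def test_intercept_only_gives_zero_fixed_share(self, two_pop_panel, two_pop_assets):
        Z, grm, pcs, _ = two_pop_assets
        truth = pg.simulate_phenotype_lmm(
            two_pop_panel, pcs, [0.02] * 10, 0.4, 0.4, seed=13, Z=Z.Z
        )
        X = np.ones((200, 1))
        fit = pg.fit_reml_single(truth.y, X, grm)
        dec = pg.decompose_variance(fit, X)
        tot = fit.tau + fit.sigma2
        assert dec.var_fixed_unbiased == pytest.approx(0.0, abs=1e-12)
        assert dec.share_genetic == pytest.approx(fit.tau / tot)
        assert dec.share_residual == pytest.approx(fit.sigma2 / tot)

    def test_shares_sum_to_one(self, two_pop_panel, two_pop_assets):
        Z, grm, pcs, _ = two_pop_assets
        truth = pg.simulate_phenotype_lmm(
            two_pop_panel, pcs, [0.02] * 10, 0.4, 0.4, seed=14, Z=Z.Z
        )
        X = np.column_stack([np.ones(200), pcs])
        dec = pg.fit_reml_single(truth.y, X, grm).decompose()
        assert dec.share_fixed + dec.share_genetic + dec.share_residual == pytest.approx(
            1.0, abs=1e-10
        )

    def test_unbiased_vs_naive_monte_carlo(self):
        """Known-truth check over 500 replicates: the corrected estimator is
        unbiased for the centered variance of X beta, while the naive
        empirical variance of X beta-hat overshoots it."""
        cfg = pg.PopulationConfig(
            n_individuals=120, n_snps=1000, n_subpops=2, fst=0.05, seed=21,
        )
        panel = pg.simulate_structured_genotypes(cfg)
        with pytest.warns(UserWarning):
            Z = standardize(panel)
        grm = compute_grm(Z)
        pcs, _ = pg.compute_pcs(Z, 6)
        X = np.column_stack([np.ones(120), pcs])
        true_var = pg.simulate_phenotype_lmm(
            panel, pcs, [0.03] * 6, 0.4, 0.4, seed=0, Z=Z.Z
        ).fixed_part.var(ddof=1)
        raw, naive = [], []
        for rep in range(500):
            truth = pg.simulate_phenotype_lmm(
                panel, pcs, [0.03] * 6, 0.4, 0.4,
                seed=np.random.default_rng([3, rep]), Z=Z.Z,
            )
            fit = pg.fit_reml_single(truth.y, X, grm)
            dec = pg.decompose_variance(fit, X)
            raw.append(dec.var_fixed_raw)
            naive.append(dec.var_fixed_naive)
        raw, naive = np.asarray(raw), np.asarray(naive)
        se = raw.std(ddof=1) / np.sqrt(len(raw))
        assert abs(raw.mean() - true_var) < 2 * se
        assert naive.mean() > true_var + 2 * naive.std(ddof=1) / np.sqrt(len(naive))


class TestFitMulti:
    def test_single_grm_matches_profile_fit(self, two_pop_panel, two_pop_assets):
        Z, grm, pcs, _ = two_pop_assets
        truth = pg.simulate_phenotype_lmm(
            two_pop_panel, pcs, [0.02] * 5, 0.4, 0.4, seed=15, Z=Z.Z
        )
        X = np.column_stack([np.ones(200), pcs[:, :5]])
        f1 = pg.fit_reml_single(truth.y, X, grm)
        f2 = GREML(truth.y, X, [grm])._fit_multi()
        np.testing.assert_allclose(
            f1.variance_components, f2.variance_components, atol=1e-6
        )
        assert f1.llf_restricted == pytest.approx(f2.llf_restricted, abs=1e-6)

    def test_identical_grms_flagged_near_singular(self, two_pop_panel, two_pop_assets):
        Z, grm, pcs, _ = two_pop_assets
        truth = pg.simulate_phenotype_lmm(
            two_pop_panel, pcs, [], tau=0.4, sigma2=0.4, seed=16, Z=Z.Z
        )
        X = np.ones((200, 1))
        fit = pg.fit_reml_multi(truth.y, X, [grm, grm])
        assert fit.ai_singular

    def test_two_block_parameter_recovery(self):
        """tau1=0.2, tau2=0.4, sigma2=0.4 at n=400: means over 25 replicates
        land within 2 Monte-Carlo SEs of the truth."""
        cfg = pg.PopulationConfig(
            n_individuals=400, n_snps=2000, n_chromosomes=2, n_subpops=1,
            fst=0.01, chrom_length_weights=(1, 1), seed=9,
        )
        panel = pg.simulate_structured_genotypes(cfg)
        Z1 = standardize(panel.subset(snps=panel.snp_indices_of_chrom(1)))
        Z2 = standardize(panel.subset(snps=panel.snp_indices_of_chrom(2)))
        g1, g2 = compute_grm(Z1), compute_grm(Z2)
        X = np.ones((400, 1))
        est = []
        for rep in range(25):
            rng = np.random.default_rng([11, rep])
            u1 = rng.normal(0, np.sqrt(0.2 / Z1.Z.shape[1]), Z1.Z.shape[1])
            u2 = rng.normal(0, np.sqrt(0.4 / Z2.Z.shape[1]), Z2.Z.shape[1])
            y = Z1.Z @ u1 + Z2.Z @ u2 + rng.normal(0, np.sqrt(0.4), 400)
            fit = pg.fit_reml_multi(y, X, [g1, g2])
            assert fit.converged
            est.append(fit.variance_components)
        est = np.asarray(est)
        se = est.std(axis=0, ddof=1) / np.sqrt(25)
        np.testing.assert_array_less(
            np.abs(est.mean(axis=0) - [0.2, 0.4, 0.4]), 2 * se
        )
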