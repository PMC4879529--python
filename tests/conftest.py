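"""Shared fixtures: panels and derived matrices are expensive, so structured
panels, GRMs and PC sets are built once per session and reused read-only."""

import numpy as np
import pytest

import pcgreml as pg
from pcgreml.genotype import compute_grm, compute_pcs, standardize


@pytest.fixture(scope="session")
def two_pop_panel():
    """Two subpopulations, F_ST = 0.05, n=200, m=2000, with covariates."""
    cfg = pg.PopulationConfig(
        n_individuals=200, n_snps=2000, n_chromosomes=4, n_subpops=2,
        fst=0.05, seed=11,
    )
    panel = pg.simulate_structured_genotypes(cfg)
    return pg.simulate_covariates(panel, seed=12)


@pytest.fixture(scope="session")
def two_pop_assets(two_pop_panel):
    """(Z, GRM with cached spectrum, 10 PCs) for the two-pop panel."""
    Z = standardize(two_pop_panel)
    grm = compute_grm(Z)
    grm.eigen
    pcs, eigvals = compute_pcs(Z, 10)
    return Z, grm, pcs, eigvals


@pytest.fixture(scope="session")
def mid_panel_assets():
    """Three subpopulations, n=300, m=2000 — used for calibration studies."""
    cfg = pg.PopulationConfig(
        n_individuals=300, n_snps=2000, n_subpops=3, fst=0.02, seed=3,
    )
    panel = pg.simulate_structured_genotypes(cfg)
    Z = standardize(panel)
    grm = compute_grm(Z)
    grm.eigen
    pcs, _ = compute_pcs(Z, 10)
    return panel, Z, grm, pcs


@pytest.fixture(scope="session")
def fig1_study():
    """The reference replicate study: one structured panel (n=600, m=6000,
    3 subpopulations, F_ST=0.02), 50 phenotype replicates with ten causal
    PCs at 2% each and tau = sigma2 = 0.4, swept at p = 0 and p = 10."""
    cfg = pg.SimulationStudyConfig(seed=1)
    return pg.run_simulation_study(cfg)


def dense_restricted_loglik(y, X, K, tau, sigma2):
    """Independent brute-force REML log-likelihood on dense matrices."""
    n, p = X.shape
    V = tau * K + sigma2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        - np.linalg.slogdet(X.T @ X)[1]
        + y @ P @ y
    )
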