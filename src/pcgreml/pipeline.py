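"""PC-sweep and replicate-study orchestration.

``pc_sweep`` refits the mixed model with 0..p leading principal components
as fixed effects and tabulates, per p: the zero-heritability LRT, the
variance components with AI standard errors, the heritability, and the
unbiased three-way variance decomposition.  The GRM eigendecomposition is
computed once and reused across every p and every replicate — the central
performance decision that makes large sweeps and replicate studies cheap.

``run_simulation_study`` wraps the full experiment: one structured panel,
one GRM and PC set, then many phenotype replicates drawn under the mixed
model with fixed PC effects, each evaluated with ``pc_sweep``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import GRM, compute_grm, compute_pcs, ld_prune, standardize
from .inference import lrt_zero_heritability
from .model import GREML, decompose_variance, heritability_with_se
from .panel import GenotypePanel
from .simulate import PopulationConfig, simulate_phenotype_lmm, simulate_structured_genotypes

SWEEP_COLUMNS = [
    "p", "lrt", "pvalue", "tau", "tau_se", "sigma2", "sigma2_se",
    "total", "total_se", "h2", "h2_se",
    "share_fixed", "share_genetic", "share_residual",
]


@dataclass
class SweepTable:
    """Per-p model summaries, mirroring the published table layout."""

    table: pd.DataFrame

    def to_tsv(self, path: str, paper_style: bool = False) -> None:
        """Full precision by default; ``paper_style`` rounds to 3 significant
        digits for visual comparison with published tables."""
        df = self.table
        if paper_style:
            df = df.copy()
            for c in df.columns:
                if c != "p":
                    df[c] = df[c].map(lambda v: float(f"{v:.3g}"))
        df.to_csv(path, sep="\t", index=False)

    def row(self, p: int) -> pd.Series:
        return self.table.set_index("p").loc[p]


def pc_sweep(y, base_covariates, grm: GRM, pcs: np.ndarray, p_list) -> SweepTable:
    """Fit the model with the first p PCs as fixed effects, for each p.

    ``base_covariates`` (may be None) are prepended after the intercept;
    duplicated values of p produce identical rows by construction.  A p for
    which the design stops being overdetermined is skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    pcs = np.asarray(pcs, dtype=float)
    p_list = list(p_list)
    if p_list and max(p_list) > pcs.shape[1]:
        raise ValueError(
            f"p={max(p_list)} requested but only {pcs.shape[1]} PCs available"
        )
    base = (
        np.empty((n, 0))
        if base_covariates is None
        else np.atleast_2d(np.asarray(base_covariates, dtype=float).reshape(n, -1))
    )
    rows = []
    for p in p_list:
        X = np.column_stack([np.ones(n), base, pcs[:, :p]])
        if X.shape[1] + 2 > n:
            warnings.warn(f"p={p}: design has {X.shape[1]} columns for n={n}; skipped")
            continue
        fit = GREML(y, X, grm).fit()
        h2, h2_se = heritability_with_se(fit)
        dec = decompose_variance(fit, X)
        lrt = lrt_zero_heritability(y, X, grm, fit_alt=fit)
        se = fit.vc_se
        rows.append(
            {
                "p": p,
                "lrt": lrt.stat,
                "pvalue": lrt.pvalue,
                "tau": fit.tau,
                "tau_se": se[0],
                "sigma2": fit.sigma2,
                "sigma2_se": se[-1],
                "total": fit.total_variance,
                "total_se": fit.total_variance_se,
                "h2": h2,
                "h2_se": h2_se,
                "share_fixed": dec.share_fixed,
                "share_genetic": dec.share_genetic,
                "share_residual": dec.share_residual,
            }
        )
    return SweepTable(table=pd.DataFrame(rows, columns=SWEEP_COLUMNS))


@dataclass
class SimulationStudyConfig:
    """Replicate study: panel + phenotype generation + sweep settings.

    Defaults encode the reference simulation design: three subpopulations,
    F_ST = 0.02, ten causal PCs at 2% of variance each, tau = sigma2 = 0.4
    (so h2 = 0.5 and the PCs jointly explain 20%).
    """

    population: PopulationConfig = field(default_factory=PopulationConfig)
    n_replicates: int = 50
    p_list: tuple = (0, 10)
    pc_shares: tuple = tuple([0.02] * 10)
    tau: float = 0.4
    sigma2: float = 0.4
    n_pcs_computed: int | None = None  # default: max(p_list, n causal)
    ld_r2_max: float = 0.1
    maf_min_prune: float = 0.05
    seed: int = 0


@dataclass
class SimulationStudySummary:
    """Mean and SD over replicates of each share and of h2, per p."""

    per_p: pd.DataFrame  # p, mean_*/sd_* columns, n_replicates
    replicates: pd.DataFrame  # long table: replicate x sweep rows
    n_replicates: int
    config: SimulationStudyConfig


def prepare_panel_inputs(config: SimulationStudyConfig):
    """Generate the panel and compute Z, GRM and PCs once.

    The GRM for REML uses all SNPs; the PCs come from the GRM of the
    MAF-filtered, LD-pruned SNP subset (pruning r2 threshold
    ``ld_r2_max``), mirroring standard practice.
    """
    from .genotype import allele_frequencies

    panel = simulate_structured_genotypes(config.population)
    Zs = standardize(panel)
    grm = compute_grm(Zs)
    freqs = allele_frequencies(panel)
    maf_ok = np.minimum(freqs, 1 - freqs) >= config.maf_min_prune
    pruned_idx = ld_prune(panel.subset(snps=np.flatnonzero(maf_ok)), r2_max=config.ld_r2_max)
    panel_pruned = panel.subset(snps=np.flatnonzero(maf_ok)[pruned_idx])
    k = config.n_pcs_computed or max(
        max(config.p_list, default=0), len(config.pc_shares), 1
    )
    pcs, eigvals = compute_pcs(standardize(panel_pruned), k)
    return panel, Zs, grm, pcs, eigvals


def replicate_seed(master_seed: int, replicate: int) -> np.random.Generator:
    """Child generator for one replicate: default_rng([master_seed, k]).

    Fixed, documented rule so that replicate k is reproducible in isolation.
    """
    return np.random.default_rng([master_seed, replicate])


def run_simulation_study(config: SimulationStudyConfig) -> SimulationStudySummary:
    """One panel, many phenotype replicates, a PC sweep per replicate."""
    panel, Zs, grm, pcs, _ = prepare_panel_inputs(config)
    records = []
    for rep in range(config.n_replicates):
        child = replicate_seed(config.seed, rep)
        truth = simulate_phenotype_lmm(
            panel,
            pcs,
            config.pc_shares,
            tau=config.tau,
            sigma2=config.sigma2,
            seed=child,
            Z=Zs.Z,
        )
        sweep = pc_sweep(truth.y, None, grm, pcs, config.p_list)
        t = sweep.table.copy()
        t.insert(0, "replicate", rep)
        records.append(t)
    replicates = pd.concat(records, ignore_index=True)
    agg = replicates.groupby("p").agg(
        mean_share_fixed=("share_fixed", "mean"),
        sd_share_fixed=("share_fixed", "std"),
        mean_share_genetic=("share_genetic", "mean"),
        sd_share_genetic=("share_genetic", "std"),
        mean_share_residual=("share_residual", "mean"),
        sd_share_residual=("share_residual", "std"),
        mean_h2=("h2", "mean"),
        sd_h2=("h2", "std"),
        n=("h2", "size"),
    ).reset_index()
    return SimulationStudySummary(
        per_p=agg,
        replicates=replicates,
        n_replicates=config.n_replicates,
        config=config,
    )
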