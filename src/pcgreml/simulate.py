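"""Synthetic structured populations and mixed-model phenotypes.

This module generates everything the estimation pipeline consumes, with
recorded ground truth:

* structured genotype panels under the Balding–Nichols model (discrete
  subpopulations, allele-frequency clines, or both), with per-individual
  birth coordinates correlated with ancestry;
* sex/age covariates with configurable moments;
* quantitative phenotypes under the linear mixed model
  ``y = X beta + Z u + e`` with fixed effects on leading principal
  components, ``u ~ N(0, (tau/m) I)`` so that ``Var(Z u) = tau * K``, and
  ``e ~ N(0, sigma2 I)``.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel, MISSING

logger = logging.getLogger(__name__)

# Default subpopulation centres (longitude degE, latitude degN), chosen to
# resemble three French recruitment cities (Bordeaux, Dijon, Montpellier).
DEFAULT_CENTERS = ((-0.58, 44.84), (5.04, 47.32), (3.88, 43.61))

# Descriptive moments used as covariate defaults: female fraction 3495/5793,
# age mean 74.30 y, age SD 5.52 y.
DEFAULT_SEX_FEMALE_PROB = 3495 / 5793
DEFAULT_AGE_MEAN = 74.30
DEFAULT_AGE_SD = 5.52

FREQ_CLIP = (0.01, 0.99)


@dataclass
class PopulationConfig:
    """Configuration of a structured synthetic population.

    Parameters
    ----------
    n_individuals, n_snps, n_chromosomes : int
        Panel dimensions; SNPs are split into ``n_chromosomes`` contiguous
        blocks with lengths proportional to ``chrom_length_weights``.
    structure_mode : {"discrete", "cline", "mixed"}
        "discrete": Balding–Nichols subpopulation frequencies only;
        "cline": smooth logit-linear frequency gradients over the map;
        "mixed": both.
    n_subpops : int
        Number of subpopulations (also the number of map centres used).
    fst : float
        Balding–Nichols divergence parameter, strictly in (0, 1).
    subpop_centers : sequence of (longitude, latitude)
        One centre per subpopulation; defaults are recycled/extended.
    subpop_weights : sequence of float
        Sampling probabilities per subpopulation; must sum to 1.
    coord_jitter_sd : float
        SD (degrees) of the Gaussian jitter of birth coordinates around the
        subpopulation centre.
    cline_strength : float
        SD of the per-SNP logit-frequency gradient (per degree).
    maf_range : (float, float)
        Range of the ancestral allele frequency (uniform draw).
    missing_rate : float
        Per-genotype missing probability (default 0, set >0 to exercise QC).
    seed : int
        Seed of the generator; identical configs give identical panels.
    """

    n_individuals: int = 600
    n_snps: int = 6000
    n_chromosomes: int = 22
    structure_mode: str = "discrete"
    n_subpops: int = 3
    fst: float = 0.02
    subpop_centers: tuple = DEFAULT_CENTERS
    subpop_weights: tuple | None = None
    coord_jitter_sd: float = 0.3
    cline_strength: float = 0.05
    maf_range: tuple = (0.05, 0.50)
    chrom_length_weights: tuple | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure_mode not in ("discrete", "cline", "mixed"):
            raise ValueError(f"unknown structure_mode {self.structure_mode!r}")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must be strictly between 0 and 1")
        if self.n_subpops > self.n_individuals:
            raise ValueError("n_subpops cannot exceed n_individuals")
        if self.subpop_weights is None:
            self.subpop_weights = tuple([1.0 / self.n_subpops] * self.n_subpops)
        w = np.asarray(self.subpop_weights, dtype=float)
        if len(w) != self.n_subpops or not np.isclose(w.sum(), 1.0):
            raise ValueError("subpop_weights must be a simplex vector of length n_subpops")
        if len(self.subpop_centers) < self.n_subpops:
            raise ValueError("need one centre per subpopulation")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < min <= max < 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")

    def chromosome_blocks(self) -> np.ndarray:
        """SNP counts per chromosome: contiguous blocks, lengths decreasing
        linearly 2:1 by default (largest-remainder rounding to sum to m)."""
        if self.chrom_length_weights is not None:
            w = np.asarray(self.chrom_length_weights, dtype=float)
            if len(w) != self.n_chromosomes:
                raise ValueError("chrom_length_weights length mismatch")
        elif self.n_chromosomes == 1:
            w = np.ones(1)
        else:
            w = np.linspace(2.0, 1.0, self.n_chromosomes)
        w = w / w.sum()
        exact = w * self.n_snps
        counts = np.floor(exact).astype(int)
        rem = self.n_snps - counts.sum()
        order = np.argsort(-(exact - counts))
        counts[order[:rem]] += 1
        if (counts == 0).any():
            raise ValueError("n_snps cannot be divided into n_chromosomes non-empty blocks")
        return counts


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_structured_genotypes(config: PopulationConfig) -> GenotypePanel:
    """Draw a structured genotype panel under the Balding–Nichols model.

    Ancestral frequencies ``p_j ~ Uniform(maf_range)``; with divergence
    ``F = fst`` each subpopulation draws
    ``p_sj ~ Beta(p_j (1-F)/F, (1-p_j)(1-F)/F)`` (mean ``p_j``, variance
    ``F p_j (1-p_j)``).  In cline/mixed mode a per-SNP logit-linear gradient
    in the birth coordinates is added.  Genotypes are ``Binomial(2, p)``.
    Frequencies falling outside (0, 1) after the cline transform are clipped
    to [0.01, 0.99]; the clip count is recorded on the panel and logged.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    k = config.n_subpops

    # subpopulation assignment and birth coordinates
    labels = rng.choice(k, size=n, p=np.asarray(config.subpop_weights, dtype=float))
    centers = np.asarray(config.subpop_centers[: k], dtype=float)
    coords = centers[labels] + rng.normal(0.0, config.coord_jitter_sd, size=(n, 2))

    # ancestral and subpopulation frequencies
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    F = config.fst
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    if config.structure_mode in ("discrete", "mixed"):
        p_sub = rng.beta(a[None, :], b[None, :], size=(k, m))
    else:
        p_sub = np.repeat(p_anc[None, :], k, axis=0)

    n_clipped = 0
    if config.structure_mode in ("cline", "mixed"):
        # per-SNP isotropic gradient over (longitude, latitude)
        grad = rng.normal(0.0, config.cline_strength, size=(2, m))
        dev = coords - centers.mean(axis=0)  # n x 2, deviation from map centre
        logit_p = _logit(np.clip(p_sub[labels], 1e-12, 1 - 1e-12)) + dev @ grad
        p_ind = _expit(logit_p)
        outside = (p_ind < FREQ_CLIP[0]) | (p_ind > FREQ_CLIP[1])
        n_clipped = int(outside.sum())
        if n_clipped:
            logger.info("clipped %d individual-level frequencies to %s", n_clipped, FREQ_CLIP)
        p_ind = np.clip(p_ind, *FREQ_CLIP)
        dosages = rng.binomial(2, p_ind).astype(np.int8)
    else:
        dosages = np.empty((n, m), dtype=np.int8)
        for s in range(k):
            rows = np.flatnonzero(labels == s)
            dosages[rows] = rng.binomial(2, p_sub[s][None, :], size=(rows.size, m)).astype(np.int8)

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosages[miss] = MISSING

    blocks = config.chromosome_blocks()
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), blocks)
    # strictly increasing positions within each chromosome (10 kb spacing)
    within = np.concatenate([np.arange(c) for c in blocks])
    pos = (within + 1) * 10_000
    snp_map = pd.DataFrame(
        {
            "chrom": chroms,
            "snp_id": [f"snp{j + 1}" for j in range(m)],
            "pos": pos,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    individuals = pd.DataFrame(
        {
            "iid": [f"ind{i + 1}" for i in range(n)],
            "sex": pd.array([None] * n, dtype="object"),
            "age": np.full(n, np.nan),
            "subpop": labels,
            "longitude": coords[:, 0],
            "latitude": coords[:, 1],
        }
    )
    return GenotypePanel(dosages, snp_map, individuals, n_clipped_freqs=n_clipped)


def simulate_covariates(
    panel: GenotypePanel,
    sex_female_prob: float = DEFAULT_SEX_FEMALE_PROB,
    age_mean: float = DEFAULT_AGE_MEAN,
    age_sd: float = DEFAULT_AGE_SD,
    seed: int = 0,
) -> GenotypePanel:
    """Fill sex and age on a panel's individuals (returns a new panel).

    Sex is Bernoulli(sex_female_prob) for "F"; age is N(age_mean, age_sd^2).
    """
    if not (0.0 <= sex_female_prob <= 1.0):
        raise ValueError("sex_female_prob must be in [0, 1]")
    if age_sd < 0:
        raise ValueError("age_sd must be non-negative")
    if panel.n_individuals == 0:
        raise ValueError("panel has no individuals")
    rng = np.random.default_rng(seed)
    n = panel.n_individuals
    female = rng.random(n) < sex_female_prob
    age = age_mean + age_sd * rng.standard_normal(n)
    individuals = panel.individuals.copy()
    individuals["sex"] = np.where(female, "F", "M")
    individuals["age"] = age
    return GenotypePanel(
        panel.dosages, panel.snp_map, individuals, n_clipped_freqs=panel.n_clipped_freqs
    )


@dataclass
class PhenotypeTruth:
    """A simulated phenotype with its exact decomposition.

    ``y = fixed_part + genetic_part + residual_part`` holds to machine
    precision; ``fixed_part`` includes both covariate and PC effects.
    """

    y: np.ndarray
    fixed_part: np.ndarray
    genetic_part: np.ndarray
    residual_part: np.ndarray
    tau_true: float
    sigma2_true: float
    pc_shares_true: np.ndarray
    pc_betas: np.ndarray = field(default_factory=lambda: np.empty(0))


def simulate_phenotype_lmm(
    panel: GenotypePanel,
    pcs: np.ndarray,
    pc_shares,
    tau: float,
    sigma2: float,
    covariate_effects: dict | None = None,
    seed: int = 0,
    v_total: float = 1.0,
    Z: np.ndarray | None = None,
) -> PhenotypeTruth:
    """Simulate a phenotype under the mixed model with PC fixed effects.

    Each PC ``i`` receives slope ``beta_i = sqrt(pc_shares[i] * v_total) /
    sd(PC_i)`` so that it contributes the requested share of the total
    variance; the genetic part is ``Z u`` with ``u ~ N(0, tau/m)`` i.i.d.
    per SNP (hence ``Var(Z u) = tau * Z Z'/m = tau * K``); the residual is
    ``N(0, sigma2)``.

    Parameters
    ----------
    pcs : ndarray (n, k)
        Column-orthogonal principal components (unit-norm eigenvectors).
    pc_shares : sequence of float, length <= k
        Target variance share per causal PC.
    covariate_effects : dict, optional
        Map from a column of ``panel.individuals`` (e.g. "age", or "sex"
        coded F=1/M=0) to a fixed-effect slope.
    Z : ndarray, optional
        Pre-standardized genotype matrix to reuse; computed from the panel
        when omitted.
    """
    from .genotype import standardize  # deferred to avoid a cycle

    n = panel.n_individuals
    pcs = np.asarray(pcs, dtype=float)
    shares = np.asarray(pc_shares, dtype=float)
    if shares.size > pcs.shape[1]:
        raise ValueError(
            f"{shares.size} PC shares requested but only {pcs.shape[1]} PCs supplied"
        )
    if shares.size and ((shares < 0).any() or (shares >= 1).any()):
        raise ValueError("pc_shares must lie in [0, 1)")
    if tau < 0 or sigma2 < 0:
        raise ValueError("variance components must be non-negative")
    budget = shares.sum() + (tau + sigma2) / v_total
    if budget > 1.0 + 1e-9:
        raise ValueError(
            f"PC shares plus variance components exceed the total variance "
            f"budget ({budget:.3f} > 1)"
        )
    # column orthogonality check (scaled)
    if shares.size:
        sub = pcs[:, : shares.size]
        gram = sub.T @ sub
        off = gram - np.diag(np.diag(gram))
        if np.abs(off).max() > 1e-6 * np.abs(np.diag(gram)).max():
            raise ValueError("pcs must be column-orthogonal")

    rng = np.random.default_rng(seed)
    betas = np.zeros(shares.size)
    fixed = np.zeros(n)
    for i, share in enumerate(shares):
        sd = pcs[:, i].std()
        betas[i] = np.sqrt(share * v_total) / sd if share > 0 else 0.0
        fixed = fixed + betas[i] * pcs[:, i]
    if covariate_effects:
        for name, slope in covariate_effects.items():
            col = panel.individuals[name]
            if name == "sex":
                vals = (col == "F").astype(float).to_numpy()
            else:
                vals = col.to_numpy(dtype=float)
            fixed = fixed + slope * vals

    if tau > 0:
        if Z is None:
            Z = standardize(panel).Z
        m = Z.shape[1]
        u = rng.normal(0.0, np.sqrt(tau / m), size=m)
        genetic = Z @ u
    else:
        genetic = np.zeros(n)
    residual = rng.normal(0.0, np.sqrt(sigma2), size=n) if sigma2 > 0 else np.zeros(n)

    y = fixed + genetic + residual
    return PhenotypeTruth(
        y=y,
        fixed_part=fixed,
        genetic_part=genetic,
        residual_part=residual,
        tau_true=tau,
        sigma2_true=sigma2,
        pc_shares_true=shares,
        pc_betas=betas,
    )
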