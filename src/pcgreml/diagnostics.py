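"""Chromosome-partitioning diagnostic for stratification and relatedness.

Heritability is estimated once per chromosome (single-GRM fits) and once
jointly (a multi-GRM fit over all chromosome GRMs), and the difference
``d_c = h2_single,c - h2_joint,c`` is regressed on chromosome length.
Without cryptic relatedness or stratification the two estimates agree: a
significantly positive intercept points to cryptic relatedness, a
significantly positive slope to population stratification (structure is
shared across chromosomes, so a lone chromosome's GRM soaks up genome-wide
stratified signal in proportion to nothing, while the joint fit divides it;
the excess grows with chromosome size).

Conventions (stated because the literature leaves them loose): per-
chromosome heritability is ``tau_c / (tau_c + sigma2_c)`` in the single fit
and ``tau_c^joint / (sum_c tau_c^joint + sigma2^joint)`` in the joint fit;
"length" defaults to the SNP count of the chromosome, with base-pair span
available via ``length_mode="bp"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotype import GRM, compute_grm, standardize
from .model import fit_reml_multi, fit_reml_single
from .panel import GenotypePanel

MIN_SNPS_PER_CHROM = 10


@dataclass
class ChromosomePartitionResult:
    """Per-chromosome estimates and the difference-vs-length regression."""

    table: pd.DataFrame  # chrom, length, tau_single, tau_joint, h2_single, h2_joint, d
    intercept: float = np.nan
    slope: float = np.nan
    intercept_se: float = np.nan
    slope_se: float = np.nan
    intercept_t: float = np.nan
    slope_t: float = np.nan
    intercept_pvalue: float = np.nan
    slope_pvalue: float = np.nan
    sigma2_joint: float = np.nan
    length_mode: str = "snps"

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)
        with open(path, "a") as fh:
            fh.write(
                f"# regression d ~ length ({self.length_mode}): "
                f"intercept={self.intercept:.6g} (se {self.intercept_se:.3g}, "
                f"p={self.intercept_pvalue:.3g}); "
                f"slope={self.slope:.6g} (se {self.slope_se:.3g}, "
                f"p={self.slope_pvalue:.3g})\n"
            )


def build_chromosome_grms(panel: GenotypePanel, min_snps: int = MIN_SNPS_PER_CHROM):
    """One GRM per chromosome from that chromosome's standardized SNPs.

    Returns (chrom ids, lengths in SNPs, lengths in bp, list of GRM);
    chromosomes with fewer than ``min_snps`` SNPs are excluded with a
    warning.
    """
    chroms, grms, len_snps, len_bp = [], [], [], []
    for chrom in panel.chromosomes:
        idx = panel.snp_indices_of_chrom(chrom)
        if len(idx) < min_snps:
            warnings.warn(
                f"chromosome {chrom} has {len(idx)} SNPs (<{min_snps}); excluded",
                stacklevel=2,
            )
            continue
        sub = panel.subset(snps=idx)
        Z = standardize(sub)
        grms.append(compute_grm(Z))
        chroms.append(chrom)
        len_snps.append(len(Z.kept_snps))
        pos = sub.snp_map["pos"]
        len_bp.append(int(pos.max() - pos.min() + 1))
    return chroms, np.array(len_snps), np.array(len_bp), grms


def chromosome_partition(
    y,
    X,
    panel: GenotypePanel,
    length_mode: str = "snps",
    grms: list | None = None,
    chrom_info: tuple | None = None,
) -> ChromosomePartitionResult:
    """Single-vs-joint per-chromosome heritability comparison.

    ``grms``/``chrom_info`` allow reuse of pre-built chromosome GRMs (and
    their cached eigendecompositions) across phenotype replicates.
    The regression is filled in by :func:`partition_regression`.
    """
    if length_mode not in ("snps", "bp"):
        raise ValueError("length_mode must be 'snps' or 'bp'")
    if grms is None:
        chroms, len_snps, len_bp, grms = build_chromosome_grms(panel)
    else:
        chroms, len_snps, len_bp = chrom_info
    if len(grms) < 3:
        raise ValueError("need at least 3 chromosomes for the diagnostic")

    tau_single, h2_single = [], []
    for g in grms:
        fit = fit_reml_single(y, X, g)
        tau_single.append(fit.tau)
        tot = fit.tau + fit.sigma2
        h2_single.append(fit.tau / tot if tot > 0 else 0.0)

    joint = fit_reml_multi(y, X, grms)
    tot_joint = joint.tau + joint.sigma2
    h2_joint = joint.taus / tot_joint if tot_joint > 0 else np.zeros(len(grms))

    lengths = len_snps if length_mode == "snps" else len_bp
    table = pd.DataFrame(
        {
            "chrom": chroms,
            "length": lengths,
            "tau_single": tau_single,
            "tau_joint": joint.taus,
            "h2_single": h2_single,
            "h2_joint": h2_joint,
            "d": np.asarray(h2_single) - h2_joint,
        }
    )
    result = ChromosomePartitionResult(
        table=table, sigma2_joint=joint.sigma2, length_mode=length_mode
    )
    return partition_regression(result)


def partition_regression(result: ChromosomePartitionResult) -> ChromosomePartitionResult:
    """OLS of the single-minus-joint difference on chromosome length.

    Two-sided t-tests on the intercept (cryptic relatedness) and the slope
    (population stratification).
    """
    table = result.table
    if len(table) < 3:
        raise ValueError("need at least 3 chromosome rows")
    x = table["length"].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError("chromosome lengths have zero variance")
    X = sm.add_constant(x)
    ols = sm.OLS(table["d"].to_numpy(dtype=float), X).fit()
    result.intercept, result.slope = ols.params
    result.intercept_se, result.slope_se = ols.bse
    result.intercept_t, result.slope_t = ols.tvalues
    result.intercept_pvalue, result.slope_pvalue = ols.pvalues
    return result
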