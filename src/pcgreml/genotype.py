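"""Genotype-matrix computations: standardization, QC, pruning, GRM, PCA.

The genomic relationship matrix follows the GREML/GCTA convention
``K = Z Z' / m`` on columns standardized to population mean 0 and variance 1
under the estimated allele frequency, so the average diagonal is close to 1
and the genetic variance component is on the phenotype scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel, MISSING


def allele_frequencies(panel: GenotypePanel) -> np.ndarray:
    """Per-SNP A1 allele frequency over non-missing genotypes.

    SNPs with every genotype missing get NaN (flagged, not raised).
    """
    if panel.n_snps == 0 or panel.n_individuals == 0:
        raise ValueError("panel is empty")
    d = panel.dosages
    obs = d != MISSING
    counts = obs.sum(axis=0)
    sums = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    if (counts == 0).any():
        warnings.warn(
            f"{int((counts == 0).sum())} SNP(s) have all genotypes missing; "
            "frequency undefined (NaN)",
            stacklevel=2,
        )
    return freqs


@dataclass
class StandardizedMatrix:
    """Standardized genotypes ``Z`` with the frequencies used for scaling.

    ``kept_snps`` maps columns of Z back to panel SNP indices (monomorphic
    or all-missing SNPs are excluded).
    """

    Z: np.ndarray
    freqs: np.ndarray
    kept_snps: np.ndarray


def standardize(panel: GenotypePanel, freqs: np.ndarray | None = None) -> StandardizedMatrix:
    """Standardize dosages: ``z = (g - 2p) / sqrt(2 p (1-p))``.

    Missing dosages are imputed to ``2p`` (z = 0).  Monomorphic SNPs
    (p <= 0 or >= 1) are excluded with a warning, never divided by zero.
    """
    if freqs is None:
        freqs = allele_frequencies(panel)
    freqs = np.asarray(freqs, dtype=float)
    poly = np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic/undefined SNP(s) "
            "from standardization",
            stacklevel=2,
        )
    kept = np.flatnonzero(poly)
    p = freqs[kept]
    g = panel.dosages[:, kept].astype(float)
    g[g == MISSING] = np.nan
    Z = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    Z[np.isnan(Z)] = 0.0  # missing imputed to the mean genotype
    return StandardizedMatrix(Z=Z, freqs=p, kept_snps=kept)


@dataclass
class QCReport:
    """Per-filter removal counts; removed + retained == input."""

    n_input: int
    n_retained: int
    removed_callrate: int
    removed_hwe: int
    removed_maf: int
    removed_all_missing: int
    thresholds: dict


def hwe_pvalues(panel: GenotypePanel) -> np.ndarray:
    """1-df chi-square Hardy–Weinberg test per SNP on genotype counts."""
    d = panel.dosages
    obs = d != MISSING
    n0 = ((d == 0) & obs).sum(axis=0).astype(float)
    n1 = (d == 1).sum(axis=0).astype(float)
    n2 = (d == 2).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (n1 + 2 * n2) / (2 * np.maximum(n, 1))
        e0 = n * (1 - p) ** 2
        e1 = n * 2 * p * (1 - p)
        e2 = n * p**2
        chi2 = np.zeros(panel.n_snps)
        for o, e in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(e > 0, (o - e) ** 2 / np.maximum(e, 1e-300), 0.0)
            chi2 += term
    pvals = stats.chi2.sf(chi2, df=1)
    # monomorphic SNPs: test undefined, treat as passing (p = 1)
    mono = (p <= 0) | (p >= 1) | (n == 0)
    pvals[mono] = 1.0
    return pvals


def qc_snps(
    panel: GenotypePanel,
    maf_min: float | None = None,
    callrate_min: float = 0.99,
    hwe_alpha: float = 1e-8,
) -> tuple[GenotypePanel, QCReport]:
    """SNP quality control: call-rate, Hardy–Weinberg, optional MAF filter.

    A SNP is retained iff call-rate >= ``callrate_min``, HWE p >=
    ``hwe_alpha``, and (when ``maf_min`` is given) ``min(p, 1-p) >= maf_min``.
    The MAF filter is off by default because it is conventionally applied
    only to the subset used for pruning/PCA.
    """
    for t in (callrate_min, hwe_alpha):
        if not (0.0 <= t <= 1.0):
            raise ValueError("thresholds must be in [0, 1]")
    if maf_min is not None and not (0.0 <= maf_min <= 1.0):
        raise ValueError("maf_min must be in [0, 1]")
    d = panel.dosages
    obs = d != MISSING
    callrate = obs.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        freqs = allele_frequencies(panel)
    all_missing = ~np.isfinite(freqs)
    keep = np.ones(panel.n_snps, dtype=bool)
    keep &= ~all_missing
    pass_call = callrate >= callrate_min
    hwe_p = hwe_pvalues(panel)
    pass_hwe = hwe_p >= hwe_alpha
    keep_after_call = keep & pass_call
    keep_after_hwe = keep_after_call & pass_hwe
    if maf_min is not None:
        maf = np.minimum(freqs, 1.0 - freqs)
        pass_maf = np.where(np.isfinite(maf), maf >= maf_min, False)
        final = keep_after_hwe & pass_maf
    else:
        final = keep_after_hwe
    report = QCReport(
        n_input=panel.n_snps,
        n_retained=int(final.sum()),
        removed_all_missing=int(all_missing.sum()),
        removed_callrate=int((keep & ~pass_call).sum()),
        removed_hwe=int((keep_after_call & ~pass_hwe).sum()),
        removed_maf=int((keep_after_hwe & ~final).sum()),
        thresholds={"maf_min": maf_min, "callrate_min": callrate_min, "hwe_alpha": hwe_alpha},
    )
    if report.n_retained == 0:
        warnings.warn("QC removed every SNP", stacklevel=2)
    return panel.subset(snps=np.flatnonzero(final)), report


def _window_r2(G: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (missing -> mean)."""
    X = G.astype(float)
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf  # constant column: correlation treated as 0
    C = (X.T @ X) / X.shape[0]
    r = C / np.outer(sd, sd)
    return r**2


def ld_prune(
    panel: GenotypePanel,
    r2_max: float = 0.1,
    window_snps: int = 50,
    step_snps: int = 5,
    exclude_regions: list | None = None,
) -> np.ndarray:
    """Greedy sliding-window LD pruning on genotypic r^2.

    Within each window of ``window_snps`` currently-kept SNPs (advancing by
    ``step_snps``, never spanning chromosomes), while any pair exceeds
    ``r2_max`` the member of the worst pair with the lower MAF is dropped
    (tie: the later position).  SNPs inside ``exclude_regions`` — (chrom,
    start, end) 0-based half-open intervals — are dropped first.  Returns
    the sorted array of retained panel SNP indices.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be at least 2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        freqs = allele_frequencies(panel)
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = np.ones(panel.n_snps, dtype=bool)

    if exclude_regions:
        chrom_arr = panel.snp_map["chrom"].to_numpy()
        pos_arr = panel.snp_map["pos"].to_numpy()
        for chrom, start, end in exclude_regions:
            mask = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr < end)
            keep[mask] = False

    pos = panel.snp_map["pos"].to_numpy()
    for chrom in panel.chromosomes:
        cidx = panel.snp_indices_of_chrom(chrom)
        start = 0
        while True:
            kept_c = cidx[keep[cidx]]
            if start >= len(kept_c):
                break
            window = kept_c[start : start + window_snps]
            if len(window) >= 2:
                r2 = _window_r2(panel.dosages[:, window])
                np.fill_diagonal(r2, 0.0)
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= r2_max:
                        break
                    a, b = window[i], window[j]
                    # drop the lower-MAF member; tie -> later position
                    if maf[a] < maf[b] or (maf[a] == maf[b] and pos[a] > pos[b]):
                        drop_local = i
                    else:
                        drop_local = j
                    keep[window[drop_local]] = False
                    r2[drop_local, :] = 0.0
                    r2[:, drop_local] = 0.0
            if len(window) < window_snps:
                break
            start += step_snps
    return np.flatnonzero(keep)


@dataclass
class GRM:
    """Genomic relationship matrix ``K = Z Z' / m`` with cached spectrum."""

    K: np.ndarray
    m_snps: int
    ids: np.ndarray | None = None
    _eigen: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.K.shape[0]

    @property
    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues descending, orthonormal eigenvectors as columns)."""
        if self._eigen is None:
            vals, vecs = np.linalg.eigh(self.K)
            order = np.argsort(vals)[::-1]
            vals, vecs = vals[order], vecs[:, order]
            if vals.min() < -1e-8:
                warnings.warn(
                    f"GRM has eigenvalue {vals.min():.3e} below -1e-8", stacklevel=2
                )
            vals = np.clip(vals, 0.0, None)
            self._eigen = (vals, vecs)
        return self._eigen

    def subset(self, idx: np.ndarray) -> "GRM":
        idx = np.asarray(idx)
        return GRM(
            K=self.K[np.ix_(idx, idx)].copy(),
            m_snps=self.m_snps,
            ids=None if self.ids is None else self.ids[idx],
        )


def compute_grm(Z: np.ndarray | StandardizedMatrix, ids: np.ndarray | None = None) -> GRM:
    """``K = Z Z' / m``, symmetrized; eigendecomposition is computed lazily."""
    if isinstance(Z, StandardizedMatrix):
        Z = Z.Z
    Z = np.asarray(Z, dtype=float)
    m = Z.shape[1]
    if m == 0:
        raise ValueError("cannot build a GRM from zero SNPs")
    K = Z @ Z.T / m
    K = (K + K.T) / 2.0
    return GRM(K=K, m_snps=m, ids=ids)


def relatedness_prune(grm: GRM, threshold: float = 0.025) -> np.ndarray:
    """Greedy removal of related individuals.

    While any off-diagonal entry among kept individuals exceeds
    ``threshold``, remove the individual in the most violating pairs
    (tie: the higher index).  Returns kept indices (sorted); afterwards all
    pairwise values are <= threshold.
    """
    K = grm.K
    n = K.shape[0]
    A = (K > threshold).astype(int)
    np.fill_diagonal(A, 0)
    kept = np.ones(n, dtype=bool)
    while True:
        deg = A.sum(axis=1)
        if deg.max(initial=0) == 0:
            break
        worst = np.flatnonzero(deg == deg.max())[-1]  # tie -> higher index
        kept[worst] = False
        A[worst, :] = 0
        A[:, worst] = 0
    idx = np.flatnonzero(kept)
    sub = K[np.ix_(idx, idx)]
    off = sub - np.diag(np.diag(sub))
    assert off.max(initial=0.0) <= threshold, "relatedness pruning post-condition"
    return idx


def compute_pcs(Z_pruned: np.ndarray | StandardizedMatrix | GRM, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components of the GRM of a pruned genotype matrix.

    Returns (PCs as unit-norm eigenvector columns, eigenvalues descending);
    each PC's sign is fixed so its largest-magnitude entry is positive.
    """
    grm = Z_pruned if isinstance(Z_pruned, GRM) else compute_grm(Z_pruned)
    if k > grm.n - 1:
        raise ValueError(f"k={k} exceeds n-1={grm.n - 1}")
    vals, vecs = grm.eigen
    pcs = vecs[:, :k].copy()
    for i in range(k):
        j = np.argmax(np.abs(pcs[:, i]))
        if pcs[j, i] < 0:
            pcs[:, i] = -pcs[:, i]
    return pcs, vals[:k].copy()
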