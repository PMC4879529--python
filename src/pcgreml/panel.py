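"""Genotype panel container shared by the simulator, QC and I/O layers.

A :class:`GenotypePanel` holds an ``n x m`` dosage matrix (counts of the A1
allele, so values in ``{0, 1, 2}`` with :data:`MISSING` for no-calls), a SNP
map (chromosome, base-pair position, allele codes) and per-individual
metadata (id, sex, age, subpopulation label, birth coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing dosage in the int8 matrix.
MISSING: int = -1

SNP_MAP_COLUMNS = ["chrom", "snp_id", "pos", "a1", "a2"]
INDIVIDUAL_COLUMNS = ["iid", "sex", "age", "subpop", "longitude", "latitude"]


@dataclass
class GenotypePanel:
    """Dosage matrix plus SNP map and individual metadata.

    Parameters
    ----------
    dosages : ndarray of int8, shape (n_individuals, n_snps)
        A1-allele counts; ``MISSING`` (-1) marks a no-call.
    snp_map : DataFrame with columns ``chrom, snp_id, pos, a1, a2``
        Base-pair positions must be strictly increasing within a chromosome.
    individuals : DataFrame with columns
        ``iid, sex, age, subpop, longitude, latitude``
        ``sex`` coded "M"/"F" (or NaN before covariates are simulated).
    n_clipped_freqs : int
        Number of per-(individual/subpop, SNP) allele frequencies the
        simulator had to clip into [0.01, 0.99]; 0 for data read from disk.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    individuals: pd.DataFrame
    n_clipped_freqs: int = 0

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if len(self.snp_map) != m:
            raise ValueError(
                f"snp_map has {len(self.snp_map)} rows for {m} SNP columns"
            )
        if len(self.individuals) != n:
            raise ValueError(
                f"individuals has {len(self.individuals)} rows for {n} samples"
            )
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values: {bad}")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def chromosomes(self) -> np.ndarray:
        """Chromosome ids in panel order (unique, order of first appearance)."""
        return self.snp_map["chrom"].unique()

    def subset(
        self,
        individuals: np.ndarray | list | None = None,
        snps: np.ndarray | list | None = None,
    ) -> "GenotypePanel":
        """Return a new panel restricted to the given index arrays."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypePanel(
            dosages=self.dosages[np.ix_(ind, snp)].copy(),
            snp_map=self.snp_map.iloc[snp].reset_index(drop=True),
            individuals=self.individuals.iloc[ind].reset_index(drop=True),
            n_clipped_freqs=self.n_clipped_freqs,
        )

    def snp_indices_of_chrom(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.snp_map["chrom"] == chrom).to_numpy())

    def write_covariates_tsv(self, path: str) -> None:
        """Write individual metadata as a PLINK-style covariate table.

        Columns: FID IID sex age subpop longitude latitude (FID == IID).
        """
        df = self.individuals.copy()
        out = pd.DataFrame(
            {
                "FID": df["iid"],
                "IID": df["iid"],
                "sex": df["sex"],
                "age": df["age"],
                "subpop": df["subpop"],
                "longitude": df["longitude"],
                "latitude": df["latitude"],
            }
        )
        out.to_csv(path, sep="\t", index=False)
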