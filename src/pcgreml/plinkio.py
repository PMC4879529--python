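"""PLINK bed/bim/fam and GCTA text GRM input/output.

The .bed codec implements the SNP-major binary layout directly: magic bytes
``0x6C 0x1B``, mode byte ``0x01``, then per SNP ``ceil(n/4)`` bytes with
individuals packed two bits each from the low bits up.  Two-bit codes map to
A1-allele dosage as 00 -> 2 (hom A1), 01 -> missing, 10 -> 1 (het),
11 -> 0 (hom A2).  ``write_plink`` then ``read_plink`` is the identity on
dosages, SNP map and ids.

GRMs interchange in the GCTA text format: ``prefix.grm.gz`` (or plain
``prefix.grm``) with one line ``i j m_snps value`` per lower-triangle pair
(1-based, j <= i) and ``prefix.grm.id`` with FID/IID columns.
"""

from __future__ import annotations

import gzip
import os

import numpy as np
import pandas as pd

from .genotype import GRM
from .panel import GenotypePanel, MISSING

_MAGIC = bytes([0x6C, 0x1B])
_MODE_SNP_MAJOR = 0x01

# two-bit code (value at bit pair) -> dosage; 01 is missing
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    pass


def write_plink(panel: GenotypePanel, prefix: str) -> None:
    """Write a panel as ``prefix.bed/.bim/.fam`` (SNP-major)."""
    n, m = panel.n_individuals, panel.n_snps
    codes = np.empty((n, m), dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[panel.dosages == dosage] = code
    nbytes = (n + 3) // 4
    padded = np.zeros((4 * nbytes, m), dtype=np.uint8)
    padded[:n] = codes
    # pack 4 individuals per byte, first individual in the low bits
    shaped = padded.reshape(nbytes, 4, m)
    packed = (
        shaped[:, 0, :]
        | (shaped[:, 1, :] << 2)
        | (shaped[:, 2, :] << 4)
        | (shaped[:, 3, :] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(bytes([_MODE_SNP_MAJOR]))
        fh.write(packed.T.tobytes())  # SNP-major: all bytes of SNP 0 first

    bim = pd.DataFrame(
        {
            "chrom": panel.snp_map["chrom"],
            "snp_id": panel.snp_map["snp_id"],
            "cm": 0,
            "pos": panel.snp_map["pos"],
            "a1": panel.snp_map["a1"],
            "a2": panel.snp_map["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    ind = panel.individuals
    sex_code = ind["sex"].map({"M": 1, "F": 2}).fillna(0).astype(int)
    fam = pd.DataFrame(
        {
            "fid": ind["iid"],
            "iid": ind["iid"],
            "pid": 0,
            "mid": 0,
            "sex": sex_code,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def read_plink(prefix: str) -> GenotypePanel:
    """Read ``prefix.bed/.bim/.fam`` into a :class:`GenotypePanel`."""
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if len(raw) < 3 or raw[:2] != _MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _MODE_SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed: mode byte 0x{raw[2]:02X} (individual-major) unsupported"
        )
    nbytes = (n + 3) // 4
    expected = 3 + nbytes * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: {len(raw)} bytes, expected {expected} for "
            f"{n} individuals x {m} SNPs"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, nbytes)
    # unpack two-bit fields, low bits first
    codes = np.empty((m, nbytes * 4), dtype=np.uint8)
    codes[:, 0::4] = data & 0b11
    codes[:, 1::4] = (data >> 2) & 0b11
    codes[:, 2::4] = (data >> 4) & 0b11
    codes[:, 3::4] = (data >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    snp_map = bim[["chrom", "snp_id", "pos", "a1", "a2"]].copy()
    individuals = pd.DataFrame(
        {
            "iid": fam["iid"].astype(str),
            "sex": fam["sex"].map({1: "M", 2: "F"}),
            "age": np.nan,
            "subpop": 0,
            "longitude": np.nan,
            "latitude": np.nan,
        }
    )
    return GenotypePanel(dosages, snp_map, individuals)


# -- GCTA text GRM ----------------------------------------------------


def write_grm_text(grm: GRM, ids, prefix: str, gzipped: bool = True) -> None:
    """Write lower-triangle triplets (``.grm.gz`` or ``.grm``) plus ``.grm.id``."""
    ids = list(ids)
    n = grm.n
    if len(ids) != n:
        raise ValueError(f"{len(ids)} ids for a {n}x{n} GRM")
    path = prefix + (".grm.gz" if gzipped else ".grm")
    opener = gzip.open if gzipped else open
    with opener(path, "wt") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.m_snps}\t{grm.K[i, j]:.17g}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for iid in ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm_text(prefix: str) -> GRM:
    """Read a GCTA text GRM; fills the upper triangle symmetrically."""
    idf = pd.read_csv(prefix + ".grm.id", sep=r"\s+", header=None, names=["fid", "iid"])
    n = len(idf)
    if os.path.exists(prefix + ".grm.gz"):
        fh = gzip.open(prefix + ".grm.gz", "rt")
    elif os.path.exists(prefix + ".grm"):
        fh = open(prefix + ".grm")
    else:
        raise FileNotFoundError(f"neither {prefix}.grm.gz nor {prefix}.grm found")
    K = np.full((n, n), np.nan)
    m_snps = 0
    with fh:
        for line in fh:
            parts = line.split()
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            if i >= n or j >= n:
                raise ValueError(
                    f"GRM entry ({i + 1},{j + 1}) exceeds the {n} ids in {prefix}.grm.id"
                )
            m_snps = int(parts[2])
            K[i, j] = K[j, i] = float(parts[3])
    if np.isnan(K).any():
        missing = int(np.isnan(K[np.tril_indices(n)]).sum())
        raise ValueError(f"{missing} missing lower-triangle entries in {prefix}")
    return GRM(K=K, m_snps=m_snps, ids=idf["iid"].to_numpy())
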