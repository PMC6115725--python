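"""Readers and writers for the genetics file formats the pipeline touches.

Supported formats:

* PLINK 1 binary genotypes (``.bed``/``.bim``/``.fam``), SNP-major only.
  Hard-call additive dosages are decoded to ``{0, 1, 2, NaN}`` counting
  copies of allele 1 (the A1 column of the ``.bim``).
* Tab-delimited summary-statistics tables with a user-supplied column map
  (GWAS consortium exports use many header dialects; no auto-detection).
* Tab-delimited phenotype/covariate tables (sample id, BMI, age, sex,
  pc1..pc10).
* Three-column score files (SNP id, effect allele, weight) consumable by
  ``plink --score``.

All text tables are tab-delimited with a header row.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLINK_MAGIC = bytes([0x6C, 0x1B])
SNP_MAJOR = 0x01

#: 2-bit PLINK code -> dosage (copies of allele 1). 0b00 -> 2, 0b01 -> missing,
#: 0b10 -> 1, 0b11 -> 0.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}

# byte -> 4 dosages, low-order bit pair first
_BYTE_LUT = np.empty((256, 4))
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_DOSAGE[(_b >> (2 * _k)) & 0b11]


class PlinkFormatError(ValueError):
    """Raised when a bed/bim/fam triple violates the PLINK 1 binary spec."""


@dataclasses.dataclass
class GenotypeMatrix:
    """Hard-call genotypes with per-SNP metadata.

    Attributes
    ----------
    samples : list of str
        Ordered, unique sample ids (the ``.fam`` IID column).
    snps : pandas.DataFrame
        One row per SNP with columns ``id``, ``chrom`` (string label),
        ``pos`` (1-based bp), ``a1``, ``a2``.
    dosages : ndarray, shape (n_samples, n_snps)
        Copies of allele 1 in {0, 1, 2}; missing calls are NaN.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ids = self.snps["id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate SNP ids: {dupes[:5]}")
        if (self.snps["pos"] < 0).any():
            raise ValueError("negative SNP positions")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2, NaN}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self) -> pd.Index:
        return pd.Index(self.snps["id"])

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            snps=self.snps.copy(),
            dosages=self.dosages[idx, :],
        )

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: j for j, s in enumerate(self.snps["id"])}
        cols = [lookup[s] for s in snp_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.iloc[cols].reset_index(drop=True),
            dosages=self.dosages[:, cols],
        )


def read_plink(prefix_or_bed, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK 1 SNP-major bed/bim/fam triple.

    Accepts either a single path prefix or explicit bed/bim/fam paths.
    """
    if bim_path is None:
        prefix = str(prefix_or_bed)
        if prefix.endswith(".bed"):
            prefix = prefix[:-4]
        bed_path = prefix + ".bed"
        bim_path = prefix + ".bim"
        fam_path = prefix + ".fam"
    else:
        bed_path = str(prefix_or_bed)

    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    samples = fam["iid"].tolist()
    if len(set(samples)) != len(samples):
        raise PlinkFormatError("duplicate sample id in fam file")

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    snps = bim[["id", "chrom", "pos", "a1", "a2"]].copy()

    raw = Path(bed_path).read_bytes()
    if len(raw) < 3 or raw[:2] != PLINK_MAGIC:
        raise PlinkFormatError("not a PLINK 1 bed file (bad magic bytes)")
    if raw[2] != SNP_MAJOR:
        raise PlinkFormatError(
            f"unsupported bed mode byte 0x{raw[2]:02x}; only SNP-major (0x01)"
        )
    n, m = len(samples), len(snps)
    bytes_per_snp = (n + 3) // 4
    expected = 3 + m * bytes_per_snp
    if len(raw) != expected:
        raise PlinkFormatError(
            f"bed file has {len(raw)} bytes, expected {expected} "
            f"for {n} samples x {m} SNPs"
        )
    if m == 0 or n == 0:
        dosages = np.empty((n, m))
    else:
        data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
        dosages = _BYTE_LUT[data].reshape(m, -1)[:, :n].T.copy()
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages)


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write a bed/bim/fam triple; ``read_plink`` round-trips it exactly."""
    prefix = str(prefix)
    n, m = G.n_samples, G.n_snps
    bytes_per_snp = (n + 3) // 4

    codes = np.where(np.isnan(G.dosages.T), 0b01,
                     np.select([G.dosages.T == 2, G.dosages.T == 1],
                               [0b00, 0b10], default=0b11)).astype(np.uint8)
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    if n:
        padded[:, :n] = codes
    # pad genotypes are code 0b00 -> zero bits, per the format
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix + ".bed", "wb") as fh:
        fh.write(PLINK_MAGIC + bytes([SNP_MAJOR]))
        fh.write(packed.tobytes())

    bim = pd.DataFrame({
        "chrom": G.snps["chrom"], "id": G.snps["id"], "cm": 0,
        "pos": G.snps["pos"], "a1": G.snps["a1"], "a2": G.snps["a2"],
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    fam = pd.DataFrame({
        "fid": G.samples, "iid": G.samples, "father": 0, "mother": 0,
        "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# summary statistics

SUMMARY_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele",
                   "beta", "se", "p", "freq", "n"]


def read_summary_stats(path, column_map: Mapping[str, str]) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV.

    Parameters
    ----------
    path : str or Path
        Tab-delimited file with a header row.
    column_map : mapping
        Maps canonical names (``id``, ``effect_allele``, ``other_allele``,
        ``beta``, ``se``, ``p``; optionally ``chrom``, ``pos``, ``freq``,
        ``n``) to the file's column headers.

    Rows violating the invariants (p outside (0, 1], negative se, freq
    outside [0, 1], effect allele equal to other allele) are dropped with a
    logged count.  Duplicate SNP ids raise.
    """
    required = ["id", "effect_allele", "other_allele", "beta", "se", "p"]
    for key in required:
        if key not in column_map:
            raise KeyError(f"column_map is missing required key {key!r}")

    df = pd.read_csv(path, sep="\t")
    for key, col in column_map.items():
        if col not in df.columns:
            raise KeyError(f"mapped column {col!r} (for {key!r}) not in file")

    out = pd.DataFrame({key: df[col] for key, col in column_map.items()})
    for key in SUMMARY_COLUMNS:
        if key not in out.columns:
            out[key] = np.nan
    out = out[SUMMARY_COLUMNS]
    out["id"] = out["id"].astype(str)

    bad = (
        ~(out["p"] > 0) | ~(out["p"] <= 1)
        | (out["se"] < 0)
        | out["beta"].isna()
        | (out["effect_allele"].astype(str) == out["other_allele"].astype(str))
    )
    freq_known = out["freq"].notna()
    bad |= freq_known & ((out["freq"] < 0) | (out["freq"] > 1))
    if bad.any():
        logger.warning("dropped %d summary-stat rows failing invariants", bad.sum())
    out = out[~bad].reset_index(drop=True)

    dupes = out["id"][out["id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicated SNP ids in summary stats: {dupes.tolist()[:5]}")
    return out


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes

PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]
PHENO_REQUIRED = ["sample_id", "bmi", "age", "sex"] + PC_COLUMNS


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype/covariate TSV (sample id, BMI, age, sex, 10 PCs)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise KeyError(f"phenotype table missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample id in phenotype table")
    if not (np.isfinite(df["bmi"]) & (df["bmi"] > 0)).all():
        raise ValueError("BMI must be finite and positive")
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# score files

def write_score_file(pgs_def, path) -> None:
    """Write a 3-column (SNP id, effect allele, weight) PLINK --score file.

    Unweighted definitions carry weight 1 for every SNP.
    """
    pgs_def.table[["id", "effect_allele", "weight"]].to_csv(
        path, sep="\t", index=False
    )


def read_score_file(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "effect_allele": str})
    missing = [c for c in ("id", "effect_allele", "weight") if c not in df.columns]
    if missing:
        raise KeyError(f"score file missing columns: {missing}")
    return df
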