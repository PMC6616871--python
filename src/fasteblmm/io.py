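"""Genotype, map, phenotype and result I/O plus quality control.

Genotype coding convention: each entry counts copies of the MAJOR allele
(A2), so 0 = A1A1 (minor homozygote), 1 = A1A2, 2 = A2A2.  Missing calls
are tracked in a separate boolean mask; downstream model code requires a
complete (imputed) matrix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "MarkerMap",
    "PhenotypeVector",
    "CovariateMatrix",
    "ScanRecord",
    "QCReport",
    "read_plink",
    "write_plink",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_marker_map_tsv",
    "write_marker_map_tsv",
    "read_phenotype_tsv",
    "read_covariates_tsv",
    "qc_filter",
    "mean_impute",
    "write_scan_results",
    "read_scan_results",
]

PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK bed codes (SNP-major): 00 hom A1, 01 missing, 10 het, 11 hom A2.
# Our convention counts the A2 (major) allele, so hom A1 -> 0, het -> 1,
# hom A2 -> 2.  Sentinel 255 marks missing while decoding.
_BED_DECODE = np.array([0, 255, 1, 2], dtype=np.uint8)
_BED_ENCODE = {0: 0b00, 1: 0b10, 2: 0b11, 255: 0b01}


class FormatError(ValueError):
    """Malformed input file."""


class ConsistencyError(ValueError):
    """Mutually inconsistent inputs (dimension or id mismatch)."""


@dataclass
class GenotypeMatrix:
    """n x m matrix of allele counts with a missing mask.

    ``codes`` may be integer (raw calls) or float (after mean imputation);
    every non-missing entry lies in [0, 2].
    """

    codes: np.ndarray
    missing_mask: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (n x m) array")
        n, m = self.codes.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 individuals and m >= 1 markers, got {n} x {m}")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, m), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, m):
            raise ValueError("missing_mask shape must match codes")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal n")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        obs = self.codes[~self.missing_mask]
        if obs.size and (np.nanmin(obs) < 0 or np.nanmax(obs) > 2):
            raise ValueError("non-missing genotype codes must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def complete_codes(self) -> np.ndarray:
        """Float codes, raising if any entry is still missing."""
        if self.has_missing:
            raise ValueError("genotype matrix has missing entries; impute first")
        return np.asarray(self.codes, dtype=float)

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes[idx], self.missing_mask[idx],
                              [self.sample_ids[i] for i in np.atleast_1d(idx)])

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes[:, idx], self.missing_mask[:, idx],
                              list(self.sample_ids))


@dataclass
class MarkerMap:
    """Per-marker records: id, chromosome label, 1-based bp position, alleles."""

    table: pd.DataFrame

    REQUIRED = ("marker_id", "chromosome", "position", "allele_minor", "allele_major")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        self.table["position"] = self.table["position"].astype(np.int64)
        if (self.table["position"] < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")

    @classmethod
    def from_arrays(cls, marker_id, chromosome, position,
                    allele_minor=None, allele_major=None) -> "MarkerMap":
        m = len(marker_id)
        return cls(pd.DataFrame({
            "marker_id": list(marker_id),
            "chromosome": [str(c) for c in chromosome],
            "position": np.asarray(position, dtype=np.int64),
            "allele_minor": list(allele_minor) if allele_minor is not None else ["A"] * m,
            "allele_major": list(allele_major) if allele_major is not None else ["G"] * m,
        }))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()

    def take(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.atleast_1d(idx)].reset_index(drop=True))


@dataclass
class PhenotypeVector:
    values: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype values must be finite")


@dataclass
class CovariateMatrix:
    """Fixed-effect design matrix including an intercept column."""

    design: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        n, r = self.design.shape
        if not self.column_names:
            self.column_names = [f"x{j}" for j in range(r)]
        if len(self.column_names) != r:
            raise ValueError("column_names length must equal number of columns")
        if np.linalg.matrix_rank(self.design) < r:
            raise ValueError("covariate design is rank deficient")

    @classmethod
    def intercept(cls, n: int) -> "CovariateMatrix":
        return cls(np.ones((n, 1)), ["intercept"])


@dataclass
class ScanRecord:
    """Single-marker association result (Wald test under the mixed model)."""

    marker_id: str
    chromosome: str
    position: int
    effect: float
    effect_variance: float
    wald: float
    p_value: float
    neg_log10_p: float
    is_na: bool = False

    @classmethod
    def na(cls, marker_id, chromosome, position) -> "ScanRecord":
        nan = float("nan")
        return cls(marker_id, chromosome, int(position), nan, nan, nan, nan, nan,
                   is_na=True)


@dataclass
class QCReport:
    n_individuals_in: int
    n_individuals_removed: int
    m_in: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    m_out: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# PLINK binary trio
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path, fam_path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a PLINK 1.x binary trio (SNP-major bed).

    bim allele 1 is taken as the minor allele and allele 2 as the major;
    returned codes count the major allele, matching the package convention
    directly (hom-A1 -> 0, het -> 1, hom-A2 -> 2).
    """
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chromosome", "marker_id", "cm", "position",
                             "allele_minor", "allele_major"],
                      dtype={"chromosome": str, "marker_id": str,
                             "allele_minor": str, "allele_major": str})
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    m, n = len(bim), len(fam)
    raw = Path(bed_path).read_bytes()
    if raw[:3] != PLINK_MAGIC:
        raise FormatError(f"{bed_path}: bad PLINK bed magic bytes {raw[:3]!r}")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise ConsistencyError(
            f"bed payload {body.size} bytes inconsistent with {n} individuals x {m} SNPs")
    # unpack 2-bit fields, little-endian within each byte
    b = body.reshape(m, bytes_per_snp)
    two_bit = np.stack([(b >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    two_bit = two_bit.reshape(m, -1)[:, :n]          # m x n
    codes = _BED_DECODE[two_bit].T.copy()            # n x m
    missing = codes == 255
    codes[missing] = 0
    g = GenotypeMatrix(codes.astype(np.int8), missing, list(fam["iid"]))
    marker_map = MarkerMap(bim[["marker_id", "chromosome", "position",
                                "allele_minor", "allele_major"]].copy())
    return g, marker_map


def write_plink(g: GenotypeMatrix, marker_map: MarkerMap, prefix) -> None:
    """Write bed/bim/fam; inverse of :func:`read_plink`."""
    if len(marker_map) != g.m:
        raise ConsistencyError("marker map length does not match genotype matrix")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.n, g.m
    codes = np.asarray(np.rint(g.codes), dtype=np.int16)
    codes = np.where(g.missing_mask, 255, codes)
    lut = np.zeros(256, dtype=np.uint8)
    for value, bits in _BED_ENCODE.items():
        lut[value] = bits
    two_bit = lut[codes.T]                            # m x n
    pad = (-n) % 4
    if pad:
        # pad samples with the 00 field (ignored on read)
        two_bit = np.hstack([two_bit, np.zeros((m, pad), dtype=np.uint8)])
    quads = two_bit.reshape(m, -1, 4)
    packed = (quads[:, :, 0] | (quads[:, :, 1] << 2)
              | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC)
        fh.write(packed.tobytes())
    bim = marker_map.table
    pd.DataFrame({
        0: bim["chromosome"], 1: bim["marker_id"], 2: 0, 3: bim["position"],
        4: bim["allele_minor"], 5: bim["allele_major"],
    }).to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    pd.DataFrame({
        0: g.sample_ids, 1: g.sample_ids, 2: 0, 3: 0, 4: 0, 5: -9,
    }).to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Plain-text formats (fixtures and small panels)
# ---------------------------------------------------------------------------

def write_genotype_tsv(g: GenotypeMatrix, marker_map: MarkerMap, path) -> None:
    df = pd.DataFrame(np.where(g.missing_mask, np.nan, g.codes),
                      index=g.sample_ids, columns=marker_map.marker_ids)
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_genotype_tsv(path, marker_map: MarkerMap) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if list(df.columns) != list(marker_map.marker_ids):
        raise ConsistencyError("genotype TSV columns do not match marker map")
    vals = df.to_numpy(dtype=float)
    missing = np.isnan(vals)
    codes = np.where(missing, 0, vals)
    if np.allclose(codes, np.rint(codes)):
        codes = np.rint(codes).astype(np.int8)
    return GenotypeMatrix(codes, missing, [str(s) for s in df.index])


def write_marker_map_tsv(marker_map: MarkerMap, path) -> None:
    marker_map.table[list(MarkerMap.REQUIRED)].to_csv(path, sep="\t", index=False)


def read_marker_map_tsv(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t", dtype={"chromosome": str,
                                                        "marker_id": str}))


def read_phenotype_tsv(path, trait: str | None = None) -> tuple[PhenotypeVector, list[str]]:
    """Read a phenotype table (first column sample_id); returns trait + ids."""
    df = pd.read_csv(path, sep="\t")
    ids = [str(s) for s in df.iloc[:, 0]]
    traits = list(df.columns[1:])
    if not traits:
        raise FormatError(f"{path}: no trait columns")
    name = trait or traits[0]
    if name not in traits:
        raise ConsistencyError(f"trait {name!r} not in {traits}")
    return PhenotypeVector(df[name].to_numpy(dtype=float), name), ids


def read_covariates_tsv(path, add_intercept: bool = True) -> tuple[CovariateMatrix, list[str]]:
    df = pd.read_csv(path, sep="\t")
    ids = [str(s) for s in df.iloc[:, 0]]
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    names = list(df.columns[1:])
    if add_intercept:
        X = np.column_stack([np.ones(len(df)), X])
        names = ["intercept"] + names
    return CovariateMatrix(X, names), ids


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def hwe_chisq_pvalue(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Hardy-Weinberg goodness-of-fit chi-square (1 df) p-value.

    Monomorphic markers fit HWE trivially (p = 1).
    """
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        return 1.0
    p = (2 * n_hom_minor + n_het) / (2 * n)
    q = 1.0 - p
    if p <= 0 or q <= 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_minor, n_het, n_hom_major], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(g: GenotypeMatrix, marker_map: MarkerMap, *,
              maf_min: float = 0.05, call_rate_min: float = 0.90,
              hwe_alpha: float = 1e-6, indiv_missing_max: float = 0.10,
              ) -> tuple[GenotypeMatrix, MarkerMap, QCReport]:
    """Apply marker/individual QC in fixed order.

    Order: individual missingness, then SNP call rate, then MAF, then
    Hardy-Weinberg (chi-square, 1 df).  Thresholds are strict ("< threshold"
    removes), so a marker exactly at the boundary is kept.  Each removed SNP
    is attributed to the first criterion it fails.
    """
    for name, v in [("maf_min", maf_min), ("call_rate_min", call_rate_min),
                    ("hwe_alpha", hwe_alpha), ("indiv_missing_max", indiv_missing_max)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if len(marker_map) != g.m:
        raise ConsistencyError("marker map length does not match genotype matrix")

    n_in, m_in = g.n, g.m
    indiv_missing = g.missing_mask.mean(axis=1)
    keep_ind = indiv_missing <= indiv_missing_max
    n_removed = int((~keep_ind).sum())
    g = g.take_samples(np.flatnonzero(keep_ind))

    obs = ~g.missing_mask
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / g.n
    codes = np.where(obs, g.codes, 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        # codes count the major allele; minor-allele freq = 1 - mean/2
        mean_code = np.where(n_obs > 0, codes.sum(axis=0) / np.maximum(n_obs, 1), 0.0)
        p_minor = 1.0 - mean_code / 2.0
        maf = np.minimum(p_minor, 1.0 - p_minor)

    fail_call = call_rate < call_rate_min
    fail_maf = ~fail_call & (maf < maf_min)

    fail_hwe = np.zeros(g.m, dtype=bool)
    candidates = np.flatnonzero(~fail_call & ~fail_maf)
    for j in candidates:
        col = g.codes[obs[:, j], j]
        counts = [int(np.sum(col == c)) for c in (0, 1, 2)]
        if hwe_chisq_pvalue(*counts) < hwe_alpha:
            fail_hwe[j] = True

    keep = ~(fail_call | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("QC removed every marker (empty panel)")
    report = QCReport(
        n_individuals_in=n_in, n_individuals_removed=n_removed, m_in=m_in,
        removed_call_rate=int(fail_call.sum()), removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe.sum()), m_out=int(keep.sum()))
    idx = np.flatnonzero(keep)
    return g.take_markers(idx), marker_map.take(idx), report


def mean_impute(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the per-SNP mean of observed codes."""
    if not g.has_missing:
        return GenotypeMatrix(np.asarray(g.codes, dtype=float),
                              np.zeros_like(g.missing_mask), list(g.sample_ids))
    obs = ~g.missing_mask
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = np.flatnonzero(n_obs == 0)
        raise ValueError(f"markers with all genotypes missing: indices {bad.tolist()}")
    codes = np.asarray(g.codes, dtype=float)
    means = np.where(obs, codes, 0.0).sum(axis=0) / n_obs
    codes = np.where(g.missing_mask, means[None, :], codes)
    return GenotypeMatrix(codes, np.zeros_like(g.missing_mask), list(g.sample_ids))


# ---------------------------------------------------------------------------
# Scan results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["marker_id", "chrom", "pos", "effect", "se", "wald", "p",
                  "neg_log10_p"]


def records_to_frame(records: Sequence[ScanRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        se = np.sqrt(r.effect_variance) if np.isfinite(r.effect_variance) else np.nan
        rows.append((r.marker_id, r.chromosome, r.position, r.effect, se,
                     r.wald, r.p_value, r.neg_log10_p))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_scan_results(records: Sequence[ScanRecord], path) -> None:
    """Write a sorted scan-result TSV; p in scientific notation (3+ sig figs)."""
    df = records_to_frame(records)
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write("{}\t{}\t{}\t{:.6g}\t{:.6g}\t{:.6g}\t{:.4e}\t{:.6g}\n".format(
                row.marker_id, row.chrom, row.pos, row.effect, row.se, row.wald,
                row.p, row.neg_log10_p))


def read_scan_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "marker_id": str})
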