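"""Marker-inferred kinship, its spectral factorization, and exclusion windows.

The kinship matrix is K = Z Z^T / d built from raw 0/1/2 allele counts,
where d is the average diagonal of Z Z^T, so mean(diag(K)) = 1.  To avoid
proximal contamination the scan uses a modified kinship K' in which the
candidate SNP and its flanking window are removed:

    K' = (Z Z^T - Z_s Z_s^T) / d

with Z_s the n x s submatrix of the removed markers and d taken from the
FULL panel (never recomputed per candidate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix, MarkerMap

__all__ = ["KinshipFactor", "ExclusionSet", "build_kinship", "exclusion_window",
           "modified_kinship", "principal_components"]

EIG_CLAMP_TOL = 1e-8


@dataclass
class KinshipFactor:
    """Kinship K with its normalizer d and eigenfactorization K = U diag(eigvals) U^T."""

    K: np.ndarray
    d: float
    U: np.ndarray
    eigvals: np.ndarray

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass
class ExclusionSet:
    """Markers removed from the kinship for one candidate SNP."""

    center_index: int
    indices: np.ndarray  # sorted, includes center_index

    @property
    def s(self) -> int:
        return len(self.indices)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: largest-magnitude element positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def build_kinship(g: GenotypeMatrix, *, center: bool = False) -> KinshipFactor:
    """K = ZZ^T / d with d = trace(ZZ^T)/n; eigenfactorization attached.

    Raw (uncentered) codes by default; ``center=True`` subtracts per-SNP
    means first (offered for comparison, not the default model).
    """
    Z = g.complete_codes()
    if center:
        Z = Z - Z.mean(axis=0, keepdims=True)
    ZZt = Z @ Z.T
    d = float(np.trace(ZZt)) / g.n
    if d <= 0:
        raise ValueError("degenerate panel: trace(ZZ^T) = 0 (all codes zero)")
    K = ZZt / d
    eigvals, U = np.linalg.eigh(K)
    if eigvals.min() < -EIG_CLAMP_TOL * max(1.0, eigvals.max()):
        raise ValueError("kinship matrix is not positive semidefinite")
    eigvals = np.clip(eigvals, 0.0, None)
    return KinshipFactor(K=K, d=d, U=_fix_signs(U), eigvals=eigvals)


def exclusion_window(marker_map: MarkerMap, k: int, half_width_bp: int) -> ExclusionSet:
    """All markers on k's chromosome within ``half_width_bp`` of k (inclusive).

    Always contains k itself; half-width 0 excludes the candidate alone.
    """
    m = len(marker_map)
    if not 0 <= k < m:
        raise IndexError(f"marker index {k} out of range for m = {m}")
    if half_width_bp < 0:
        raise ValueError("half_width_bp must be >= 0")
    chrom = marker_map.chromosomes
    pos = marker_map.positions
    same = chrom == chrom[k]
    near = np.abs(pos - pos[k]) <= half_width_bp
    indices = np.flatnonzero(same & near)
    if k not in indices:  # pragma: no cover - guaranteed by construction
        indices = np.sort(np.append(indices, k))
    return ExclusionSet(center_index=k, indices=indices)


def modified_kinship(kf: KinshipFactor, g: GenotypeMatrix,
                     ex: ExclusionSet) -> np.ndarray:
    """K' = (ZZ^T - Z_s Z_s^T)/d, using d from the full-panel kinship.

    Materializes the n x n matrix; the genome scan itself uses the Woodbury
    downdate instead and never forms K'.  This function exists for small
    problems and as the dense reference.
    """
    Z = g.complete_codes()
    Zs = Z[:, ex.indices]
    Kp = kf.K - (Zs @ Zs.T) / kf.d
    return (Kp + Kp.T) / 2.0


def write_kinship_tsv(kf: KinshipFactor, sample_ids, path) -> None:
    """Square kinship TSV with sample-id header; normalizer d in a sidecar."""
    import pandas as pd
    ids = [str(s) for s in sample_ids]
    pd.DataFrame(kf.K, index=ids, columns=ids).to_csv(path, sep="\t",
                                                      index_label="sample_id")
    with open(str(path) + ".d", "w") as fh:
        fh.write(f"{kf.d!r}\n")


def read_kinship_tsv(path) -> tuple[KinshipFactor, list[str]]:
    """Inverse of :func:`write_kinship_tsv`; recomputes the eigenfactors."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    K = df.to_numpy(dtype=float)
    with open(str(path) + ".d") as fh:
        d = float(fh.read().strip())
    eigvals, U = np.linalg.eigh((K + K.T) / 2.0)
    eigvals = np.clip(eigvals, 0.0, None)
    return (KinshipFactor(K=K, d=d, U=_fix_signs(U), eigvals=eigvals),
            [str(s) for s in df.index])


def principal_components(kf: KinshipFactor, n_pc: int) -> np.ndarray:
    """Top eigenvectors of K scaled by sqrt(eigenvalue), for structure covariates."""
    if not 1 <= n_pc < kf.n:
        raise ValueError(f"n_pc must satisfy 1 <= n_pc < n = {kf.n}, got {n_pc}")
    order = np.argsort(-kf.eigvals, kind="stable")[:n_pc]
    return kf.U[:, order] * np.sqrt(kf.eigvals[order])[None, :]
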