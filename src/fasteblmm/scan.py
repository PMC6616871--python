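"""Single-marker genome scan with a Woodbury leave-window-out kinship.

For candidate SNP k the scan model is y = X beta + z_k gamma_k + xi + e with
xi ~ N(0, K' phi^2), so the phenotypic covariance is V_k sigma^2 with

    V_k = K' lambda + I = H - (lambda/d) Z_s Z_s^T,      H = K lambda + I,

where Z_s holds the excluded window.  H is diagonal in the kinship
eigenbasis, so V_k^-1 is applied through the Woodbury identity for a rank-s
downdate:

    V^-1 = A^-1 + A^-1 B (I_s - B^T A^-1 B)^-1 B^T A^-1,
    A = H,  B = sqrt(lambda/d) Z_s.

V_k equals (lambda/d) Z_{-s} Z_{-s}^T + I and is therefore positive
definite, so the s x s capacitance matrix is invertible.  gamma_k and its
variance come from GLS normal equations (identical to the mixed-model-
equation BLUE); the Wald statistic gamma^2/var(gamma) is referred to
chi-square with 1 df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .io import GenotypeMatrix, MarkerMap, ScanRecord
from .kinship import ExclusionSet, KinshipFactor, exclusion_window
from .reml import NullModelFit, _as_design, _as_vector

__all__ = ["ScanEngine", "downdate_solve", "scan_marker", "wald_pvalue",
           "genome_scan", "bonferroni_threshold"]

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)
P_FLOOR = float(np.finfo(np.float64).tiny)


@dataclass
class ScanEngine:
    """Precomputed machinery for scanning every SNP at a fixed null fit.

    lambda_hat and sigma2_hat are frozen from the null model for the whole
    scan (the variance component is treated as known, plug-in style).
    """

    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    kinship: KinshipFactor
    null_fit: NullModelFit
    X: np.ndarray
    y: np.ndarray
    window_halfwidth_bp: int = 500_000
    exclude_window: bool = True
    reprofile_sigma2: bool = False
    log_every: int = 0

    Z: np.ndarray = field(init=False, repr=False)
    Z_star: np.ndarray = field(init=False, repr=False)
    X_star: np.ndarray = field(init=False, repr=False)
    y_star: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.X = _as_design(self.X, self.genotypes.n)
        self.y = _as_vector(self.y)
        n = self.genotypes.n
        if len(self.y) != n or self.X.shape[0] != n or self.kinship.n != n:
            raise ValueError("phenotype/design/kinship dimensions disagree")
        if len(self.marker_map) != self.genotypes.m:
            raise ValueError("marker map does not match genotype matrix")
        self.Z = self.genotypes.complete_codes()
        U = self.kinship.U
        self.Z_star = U.T @ self.Z
        self.X_star = U.T @ self.X
        self.y_star = U.T @ self.y

    @property
    def lam(self) -> float:
        return self.null_fit.lambda_hat

    @property
    def n(self) -> int:
        return self.genotypes.n

    @property
    def m(self) -> int:
        return self.genotypes.m

    def exclusion_for(self, k: int) -> ExclusionSet | None:
        if not self.exclude_window:
            return None
        return exclusion_window(self.marker_map, k, self.window_halfwidth_bp)

    # -- rotated-space solver ------------------------------------------------

    def _solve_rotated(self, ex: ExclusionSet | None, rhs_star: np.ndarray
                       ) -> np.ndarray:
        """V_k^-1 applied to rhs, both in the kinship eigenbasis."""
        lam = self.lam
        w = 1.0 / (self.kinship.eigvals * lam + 1.0)
        rhs2 = rhs_star[:, None] if rhs_star.ndim == 1 else rhs_star
        Ainv_rhs = w[:, None] * rhs2
        if ex is None or ex.s == 0 or lam == 0.0:
            return Ainv_rhs if rhs_star.ndim > 1 else Ainv_rhs[:, 0]
        B = np.sqrt(lam / self.kinship.d) * self.Z_star[:, ex.indices]
        T = w[:, None] * B                       # A^-1 B
        C = np.eye(ex.s) - B.T @ T               # capacitance I_s - B^T A^-1 B
        try:
            cf = sla.cho_factor(C, lower=True)
            out = Ainv_rhs + T @ sla.cho_solve(cf, T.T @ rhs2)
        except sla.LinAlgError:
            warnings.warn("capacitance matrix numerically singular; "
                          "falling back to dense solve", RuntimeWarning)
            Vstar = np.diag(self.kinship.eigvals * lam + 1.0) - B @ B.T
            out = np.linalg.solve(Vstar, rhs2)
        return out if rhs_star.ndim > 1 else out[:, 0]


def downdate_solve(engine: ScanEngine, ex: ExclusionSet | None,
                   rhs: np.ndarray) -> np.ndarray:
    """Return V_k^-1 rhs in the original coordinates (rhs is n x q or n)."""
    rhs = np.asarray(rhs, dtype=float)
    rhs_star = engine.kinship.U.T @ rhs
    out_star = engine._solve_rotated(ex, rhs_star)
    return engine.kinship.U @ out_star


def wald_pvalue(wald: float) -> float:
    """Upper-tail chi-square(1 df) p-value, floored at the smallest normal."""
    if wald < 0:
        raise ValueError("Wald statistic must be >= 0")
    return max(float(stats.chi2.sf(wald, df=1)), P_FLOOR)


def _neg_log10_p(wald: float) -> float:
    """-log10(p) computed from the log survival function (underflow safe)."""
    return float(-stats.chi2.logsf(wald, df=1) / LN10)


def scan_marker(engine: ScanEngine, k: int) -> ScanRecord:
    """Wald test of SNP k under covariance (K' lambda + I) sigma^2.

    Monomorphic SNPs, or SNPs lying in the column span of X, yield an NA
    record rather than raising.
    """
    mm = engine.marker_map
    mid = str(mm.marker_ids[k])
    chrom = str(mm.chromosomes[k])
    pos = int(mm.positions[k])
    z = engine.Z[:, k]
    if np.ptp(z) == 0.0:
        return ScanRecord.na(mid, chrom, pos)

    ex = engine.exclusion_for(k)
    W_star = np.column_stack([engine.X_star, engine.Z_star[:, k]])
    M = engine._solve_rotated(ex, np.column_stack([W_star, engine.y_star]))
    Vi_W, Vi_y = M[:, :-1], M[:, -1]
    G = W_star.T @ Vi_W                       # W^T V^-1 W
    b = W_star.T @ Vi_y                       # W^T V^-1 y
    G = (G + G.T) / 2.0
    try:
        cf = sla.cho_factor(G, lower=True)
    except sla.LinAlgError:
        return ScanRecord.na(mid, chrom, pos)
    # collinearity guard: Cholesky succeeds but last pivot ~ 0
    if cf[0][-1, -1] ** 2 < 1e-10 * abs(G[-1, -1]):
        return ScanRecord.na(mid, chrom, pos)
    theta = sla.cho_solve(cf, b)
    Ginv_last = sla.cho_solve(cf, np.eye(len(b))[:, -1])[-1]
    gamma = float(theta[-1])

    sigma2 = engine.null_fit.sigma2_hat
    if engine.reprofile_sigma2:
        resid_star = engine.y_star - W_star @ theta
        Vi_r = engine._solve_rotated(ex, resid_star)
        dof = engine.n - W_star.shape[1]
        sigma2 = float(resid_star @ Vi_r) / dof
    var_gamma = float(sigma2 * Ginv_last)
    if var_gamma <= 0:
        return ScanRecord.na(mid, chrom, pos)
    wald = gamma * gamma / var_gamma
    return ScanRecord(mid, chrom, pos, gamma, var_gamma, wald,
                      wald_pvalue(wald), _neg_log10_p(wald))


def genome_scan(engine: ScanEngine) -> list[ScanRecord]:
    """Scan every SNP in map order; NA records preserved."""
    records = []
    n_na = 0
    for k in range(engine.m):
        rec = scan_marker(engine, k)
        n_na += rec.is_na
        records.append(rec)
        if engine.log_every and (k + 1) % engine.log_every == 0:
            logger.info("scanned %d / %d SNPs", k + 1, engine.m)
    if n_na:
        logger.info("scan complete: %d of %d SNPs untestable (NA)", n_na, engine.m)
    return records


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide per-test threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
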