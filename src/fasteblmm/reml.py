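"""Restricted maximum likelihood for the null mixed model.

Null model: y = X beta + xi + e with xi ~ N(0, K phi^2), e ~ N(0, I sigma^2).
With lambda = phi^2 / sigma^2 the covariance is (K lambda + I) sigma^2 =
H sigma^2.  After rotating by the eigenvectors of K (y* = U^T y, X* = U^T X),
H becomes diagonal, so the restricted log-likelihood needs only the sums

    ln|H|       = sum_j ln(delta_j lambda + 1)
    a^T H^-1 b  = sum_j a*_j b*_j / (delta_j lambda + 1)

and profiling beta and sigma^2 out leaves a one-dimensional problem in
lambda, maximized by safeguarded Newton iteration on ln(lambda).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import CovariateMatrix, PhenotypeVector
from .kinship import KinshipFactor

__all__ = ["RotatedData", "NullModelFit", "rotate", "logdet_H", "quad_form",
           "profiled_reml_loglik", "fit_null"]

LAMBDA_MIN = 1e-5
LAMBDA_MAX = 1e5


@dataclass
class RotatedData:
    """Phenotype and design rotated into the kinship eigenbasis."""

    y_star: np.ndarray
    X_star: np.ndarray
    eigvals: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y_star)

    @property
    def r(self) -> int:
        return self.X_star.shape[1]


@dataclass
class NullModelFit:
    """REML estimates under the null (no candidate SNP, full kinship)."""

    lambda_hat: float
    sigma2_hat: float
    phi2_hat: float
    beta_hat: np.ndarray
    restricted_loglik: float
    n_iter: int
    converged: bool
    status: str = "ok"

    def summary_text(self) -> str:
        lines = [
            f"lambda_hat\t{self.lambda_hat:.8g}",
            f"sigma2\t{self.sigma2_hat:.8g}",
            f"phi2\t{self.phi2_hat:.8g}",
            f"loglik\t{self.restricted_loglik:.8g}",
            f"iterations\t{self.n_iter}",
            f"converged\t{self.converged}",
            f"status\t{self.status}",
        ]
        return "\n".join(lines) + "\n"


def _as_vector(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        return y.values
    return np.asarray(y, dtype=float).ravel()


def _as_design(X, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    if isinstance(X, CovariateMatrix):
        return X.design
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def rotate(y, X, kf: KinshipFactor) -> RotatedData:
    """y* = U^T y, X* = U^T X (orthogonal rotation, norm preserving)."""
    yv = _as_vector(y)
    Xd = _as_design(X, len(yv))
    if len(yv) != kf.n or Xd.shape[0] != kf.n:
        raise ValueError("dimension mismatch between phenotype/design and kinship")
    return RotatedData(y_star=kf.U.T @ yv, X_star=kf.U.T @ Xd, eigvals=kf.eigvals)


def logdet_H(lam: float, eigvals: np.ndarray) -> float:
    """ln|H| = sum_j ln(delta_j lambda + 1) for H = K lambda + I."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    w = np.asarray(eigvals) * lam + 1.0
    if np.any(w <= 0):
        raise ValueError("delta_j * lambda + 1 <= 0: H not positive definite")
    return float(np.sum(np.log(w)))


def quad_form(a_star, b_star, lam: float, eigvals: np.ndarray):
    """a^T H^-1 b in the eigenbasis: sum_j a*_j b*_j / (delta_j lambda + 1).

    Accepts vectors or matrices (columns treated independently); returns a
    scalar for two vectors, otherwise the matrix of pairwise forms.
    """
    a = np.asarray(a_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    if a.shape[0] != b.shape[0] or a.shape[0] != len(eigvals):
        raise ValueError("quad_form operands must share the eigenbasis dimension")
    w = 1.0 / (np.asarray(eigvals) * lam + 1.0)
    a2 = a[:, None] if a.ndim == 1 else a
    b2 = b[:, None] if b.ndim == 1 else b
    out = (a2 * w[:, None]).T @ b2
    if a.ndim == 1 and b.ndim == 1:
        return float(out[0, 0])
    return out


def profiled_reml_loglik(lam: float, rd: RotatedData
                         ) -> tuple[float, np.ndarray, float]:
    """Profiled restricted log-likelihood L(lambda) with beta, sigma^2 plugged in.

    Includes all constant terms, so values are absolute log-likelihoods:

        L = -1/2 [ (n-r) ln(2 pi sigma2_hat) + (n-r) + ln|H| + ln|X*^T H^-1 X*| ]
    """
    n, r = rd.n, rd.r
    XtHX = quad_form(rd.X_star, rd.X_star, lam, rd.eigvals)
    XtHX = np.atleast_2d(XtHX)
    XtHy = quad_form(rd.X_star, rd.y_star, lam, rd.eigvals).ravel()
    sign, logdet_XtHX = np.linalg.slogdet(XtHX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X*^T H^-1 X* is singular (rank-deficient design)")
    beta = np.linalg.solve(XtHX, XtHy)
    resid = rd.y_star - rd.X_star @ beta
    sigma2 = quad_form(resid, resid, lam, rd.eigvals) / (n - r)
    if sigma2 <= 0:
        raise FloatingPointError("profiled sigma^2 is non-positive")
    L = -0.5 * ((n - r) * (math.log(2.0 * math.pi * sigma2) + 1.0)
                + logdet_H(lam, rd.eigvals) + logdet_XtHX)
    return float(L), beta, float(sigma2)


def _golden_section(f, lo: float, hi: float, tol: float = 1e-10,
                    max_iter: int = 200) -> float:
    """Maximize f on [lo, hi] by golden-section search."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def fit_null(y, X, kf: KinshipFactor, *,
             lambda_bounds: tuple[float, float] = (LAMBDA_MIN, LAMBDA_MAX),
             init_lambda: float = 1.0, tol: float = 1e-8, max_iter: int = 50,
             ) -> NullModelFit:
    """Maximize the profiled restricted likelihood over lambda.

    Newton iteration on u = ln(lambda) with finite-difference derivatives,
    step clipped to |du| <= 2.  If the curvature is non-negative or the step
    leaves the bracket, falls back to golden-section search.  The result is
    cross-checked against a coarse grid on ln(lambda) and refined from the
    grid optimum if that beats the Newton point (guards against multimodal
    profiles).  Boundary optima and flat (unidentifiable) likelihoods are
    flagged in ``status``.
    """
    rd = rotate(y, X, kf)
    if rd.n <= rd.r:
        raise ValueError("need n > r (more individuals than fixed effects)")
    lo, hi = lambda_bounds
    ulo, uhi = math.log(lo), math.log(hi)

    def f(u: float) -> float:
        return profiled_reml_loglik(math.exp(u), rd)[0]

    # flat-likelihood detection (e.g. K = I makes L constant in lambda)
    probes = np.linspace(ulo, uhi, 7)
    probe_vals = np.array([f(u) for u in probes])
    if not np.all(np.isfinite(probe_vals)):
        raise FloatingPointError("non-finite restricted likelihood at probe points")
    if probe_vals.max() - probe_vals.min() < 1e-10 * max(1.0, abs(probe_vals).max()):
        lam = float(np.clip(init_lambda, lo, hi))
        L, beta, sigma2 = profiled_reml_loglik(lam, rd)
        return NullModelFit(lam, sigma2, lam * sigma2, beta, L, 0,
                            converged=False, status="unidentifiable")

    u = math.log(float(np.clip(init_lambda, lo, hi)))
    h = 1e-4
    n_iter = 0
    newton_ok = True
    for n_iter in range(1, max_iter + 1):
        fp, f0, fm = f(u + h), f(u), f(u - h)
        grad = (fp - fm) / (2.0 * h)
        curv = (fp - 2.0 * f0 + fm) / (h * h)
        if curv >= -1e-12:
            newton_ok = False
            break
        step = -grad / curv
        step = float(np.clip(step, -2.0, 2.0))
        u_new = u + step
        if not ulo <= u_new <= uhi:
            newton_ok = False
            break
        u = u_new
        if abs(step) < tol:
            break
    if not newton_ok:
        u = _golden_section(f, ulo, uhi)

    # safeguard: coarse global grid; refine from its optimum if it wins
    grid = np.linspace(ulo, uhi, 129)
    grid_vals = np.array([f(g) for g in grid])
    j = int(np.argmax(grid_vals))
    if grid_vals[j] > f(u) + 1e-8:
        a = grid[max(j - 1, 0)]
        b = grid[min(j + 1, len(grid) - 1)]
        u = _golden_section(f, a, b)

    lam = float(np.clip(math.exp(u), lo, hi))
    L, beta, sigma2 = profiled_reml_loglik(lam, rd)
    status = "ok"
    if lam <= lo * (1 + 1e-6) or lam >= hi * (1 - 1e-6):
        status = "boundary"
    return NullModelFit(lambda_hat=lam, sigma2_hat=sigma2, phi2_hat=lam * sigma2,
                        beta_hat=beta, restricted_loglik=L, n_iter=n_iter,
                        converged=True, status=status)
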