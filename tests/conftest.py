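"""Shared fixtures and independent dense-algebra oracles.

The oracles deliberately avoid the package's spectral/Woodbury code paths:
they materialize H, K' and V and use generic dense linear algebra, so they
can vouch for the fast implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from fasteblmm.io import GenotypeMatrix, MarkerMap


# ---------------------------------------------------------------------------
# dense oracles
# ---------------------------------------------------------------------------

def dense_restricted_loglik(lam: float, y: np.ndarray, X: np.ndarray,
                            K: np.ndarray) -> float:
    """Restricted log-likelihood via dense inverses/determinants of H = K lam + I."""
    n, r = X.shape[0], X.shape[1]
    H = K * lam + np.eye(len(y))
    Hinv = np.linalg.inv(H)
    XtHiX = X.T @ Hinv @ X
    beta = np.linalg.solve(XtHiX, X.T @ Hinv @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ Hinv @ resid) / (n - r)
    _, ld_H = np.linalg.slogdet(H)
    _, ld_X = np.linalg.slogdet(XtHiX)
    return -0.5 * ((n - r) * (math.log(2 * math.pi * sigma2) + 1.0) + ld_H + ld_X)


def dense_gls_marker(y: np.ndarray, X: np.ndarray, z: np.ndarray,
                     Kprime: np.ndarray, lam: float, sigma2: float
                     ) -> tuple[float, float, float]:
    """GLS effect/variance/Wald for one SNP with K' materialized."""
    V = Kprime * lam + np.eye(len(y))
    Vinv = np.linalg.inv(V)
    W = np.column_stack([X, z])
    G = W.T @ Vinv @ W
    theta = np.linalg.solve(G, W.T @ Vinv @ y)
    gamma = float(theta[-1])
    var_gamma = float(sigma2 * np.linalg.inv(G)[-1, -1])
    return gamma, var_gamma, gamma * gamma / var_gamma


def brute_force_window(chrom: np.ndarray, pos: np.ndarray, k: int,
                       half_width: int) -> np.ndarray:
    """O(m) scan for the exclusion window."""
    return np.array([j for j in range(len(pos))
                     if chrom[j] == chrom[k] and abs(int(pos[j]) - int(pos[k]))
                     <= half_width])


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def random_panel(rng: np.random.Generator, n: int, m: int,
                 n_chrom: int = 2, spacing: int = 100_000
                 ) -> tuple[GenotypeMatrix, MarkerMap]:
    """Small random polymorphic panel with a simple map."""
    while True:
        codes = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        if (np.ptp(codes, axis=0) > 0).all():
            break
    per = int(np.ceil(m / n_chrom))
    chrom = [str(1 + j // per) for j in range(m)]
    pos = [spacing * (1 + j % per) for j in range(m)]
    g = GenotypeMatrix(codes, np.zeros((n, m), dtype=bool),
                       [f"i{i}" for i in range(n)])
    return g, MarkerMap.from_arrays([f"s{j}" for j in range(m)], chrom, pos)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def small_panel(rng):
    return random_panel(rng, n=12, m=8)
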