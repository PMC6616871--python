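"""scikit-learn style front end for the leave-window-out mixed-model scan."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import CovariateMatrix, GenotypeMatrix, MarkerMap, mean_impute, records_to_frame
from .kinship import build_kinship, principal_components
from .reml import fit_null
from .scan import ScanEngine, bonferroni_threshold, genome_scan

__all__ = ["FastEBLMMScanner"]


class FastEBLMMScanner(BaseEstimator):
    """Single-marker mixed-model GWAS with kinship leave-window-out exclusion.

    The scan fits the null linear mixed model y = X beta + xi + e with
    xi ~ N(0, K phi^2) by spectral REML, freezes the variance ratio
    lambda = phi^2/sigma^2, and then tests each SNP as a fixed effect under
    a modified kinship K' from which the candidate and its flanking window
    are removed (Woodbury rank-s downdate; K' is never materialized).

    Parameters
    ----------
    window_halfwidth_bp : int, default 500_000
        Half-width of the exclusion window, so the default spans 1 Mb
        around the candidate.  0 excludes the candidate SNP alone.
    exclude_window : bool, default True
        False runs the classical inclusion-kinship scan (no exclusion),
        provided as the proximal-contamination comparator.
    n_pcs : int, default 0
        Kinship principal components appended to the covariates.
    alpha : float, default 0.05
        Genome-wide level for the Bonferroni per-test threshold alpha/m.
    lambda_bounds : tuple, default (1e-5, 1e5)
        Search bracket for the REML variance ratio.
    reprofile_sigma2 : bool, default False
        Re-estimate sigma^2 per SNP from GLS residuals instead of reusing
        the null REML estimate in the Wald variance.
    center_kinship : bool, default False
        Center genotype codes before forming K (comparison option; the
        default follows the raw-code definition K = ZZ^T/d).

    Attributes
    ----------
    lambda_hat_, sigma2_hat_, phi2_hat_, beta_hat_ : null REML estimates.
    null_fit_ : full :class:`~fasteblmm.reml.NullModelFit`.
    kinship_ : :class:`~fasteblmm.kinship.KinshipFactor` of the panel.
    results_ : per-SNP DataFrame (effect, se, wald, p, neg_log10_p).
    records_ : list of :class:`~fasteblmm.io.ScanRecord` in map order.
    threshold_ : Bonferroni per-test threshold alpha/m.

    Examples
    --------
    >>> scanner = FastEBLMMScanner(window_halfwidth_bp=500_000)
    >>> scanner.fit(codes, phenotype, marker_map=marker_map)  # doctest: +SKIP
    >>> hits = scanner.results_[scanner.results_.p < scanner.threshold_]
    """

    def __init__(self, window_halfwidth_bp: int = 500_000,
                 exclude_window: bool = True, n_pcs: int = 0,
                 alpha: float = 0.05,
                 lambda_bounds: tuple[float, float] = (1e-5, 1e5),
                 reprofile_sigma2: bool = False,
                 center_kinship: bool = False):
        self.window_halfwidth_bp = window_halfwidth_bp
        self.exclude_window = exclude_window
        self.n_pcs = n_pcs
        self.alpha = alpha
        self.lambda_bounds = lambda_bounds
        self.reprofile_sigma2 = reprofile_sigma2
        self.center_kinship = center_kinship

    def _coerce_genotypes(self, X) -> GenotypeMatrix:
        if isinstance(X, GenotypeMatrix):
            return mean_impute(X) if X.has_missing else X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("genotypes must be an n x m matrix")
        missing = np.isnan(arr)
        g = GenotypeMatrix(np.where(missing, 0.0, arr), missing,
                           [f"s{i}" for i in range(arr.shape[0])])
        return mean_impute(g) if missing.any() else g

    def fit(self, X, y, *, marker_map: MarkerMap | None = None,
            covariates=None) -> "FastEBLMMScanner":
        """Fit the null model and scan every SNP.

        Parameters
        ----------
        X : n x m genotype codes (array with NaN for missing, or GenotypeMatrix).
        y : length-n phenotype (array or PhenotypeVector).
        marker_map : marker positions; without one, each SNP is placed on
            its own synthetic chromosome, so window exclusion reduces to
            candidate-only exclusion.
        covariates : optional n x r design (array or CovariateMatrix);
            an intercept is always included.
        """
        g = self._coerce_genotypes(X)
        if marker_map is None:
            marker_map = MarkerMap.from_arrays(
                [f"snp{j}" for j in range(g.m)],
                [f"c{j}" for j in range(g.m)],
                np.full(g.m, 1_000_000, dtype=np.int64))
        if len(marker_map) != g.m:
            raise ValueError("marker_map length does not match genotype matrix")

        n = g.n
        design = np.ones((n, 1))
        names = ["intercept"]
        if covariates is not None:
            C = covariates.design if isinstance(covariates, CovariateMatrix) \
                else np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != n:
                raise ValueError("covariate rows do not match phenotype length")
            # drop any constant column: the intercept is already present
            keep = [j for j in range(C.shape[1]) if np.ptp(C[:, j]) > 0]
            design = np.column_stack([design, C[:, keep]])
            names += [f"cov{j}" for j in keep]

        kf = build_kinship(g, center=self.center_kinship)
        if self.n_pcs:
            pcs = principal_components(kf, self.n_pcs)
            design = np.column_stack([design, pcs])
            names += [f"pc{j + 1}" for j in range(self.n_pcs)]

        null = fit_null(y, design, kf, lambda_bounds=self.lambda_bounds)
        engine = ScanEngine(
            genotypes=g, marker_map=marker_map, kinship=kf, null_fit=null,
            X=design, y=y, window_halfwidth_bp=self.window_halfwidth_bp,
            exclude_window=self.exclude_window,
            reprofile_sigma2=self.reprofile_sigma2)
        records = genome_scan(engine)

        self.n_features_in_ = g.m
        self.covariate_names_ = names
        self.kinship_ = kf
        self.null_fit_ = null
        self.lambda_hat_ = null.lambda_hat
        self.sigma2_hat_ = null.sigma2_hat
        self.phi2_hat_ = null.phi2_hat
        self.beta_hat_ = null.beta_hat
        self.engine_ = engine
        self.records_ = records
        self.results_ = records_to_frame(records)
        self.threshold_ = bonferroni_threshold(self.alpha, g.m)
        return self

    def significant(self) -> pd.DataFrame:
        """Rows of ``results_`` passing the Bonferroni threshold."""
        if not hasattr(self, "results_"):
            raise AttributeError("call fit() first")
        return self.results_[self.results_["p"] < self.threshold_]
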