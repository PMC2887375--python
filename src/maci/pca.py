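"""NIPALS principal component analysis with distance-to-model diagnostics.

The feature table ``X`` (frames x wavelet coefficients, or frames x track
coordinates) is modelled after column mean-centering as

    X_c = T P' + E

with scores ``T`` (n x k), orthonormal loadings ``P`` (p x k) and residuals
``E``.  Components are extracted sequentially with the nonlinear iterative
partial least squares (NIPALS) algorithm and deflation, which is practical
when p is much larger than n, as it is for wavelet coefficient tables.

DModX, the distance to the model in X, is each observation's residual
standard deviation normalised by the pooled residual standard deviation of
the training set; the critical limit at a significance level alpha comes
from an F-quantile, following the standard chemometric (SIMCA-style)
convention for mean-centered models (one extra degree of freedom consumed by
the centering):

    s_i   = sqrt( sum_j e_ij^2 / (p - k) )
    s_0   = sqrt( sum_ij e_ij^2 / ((n - k - 1) (p - k)) )
    DModX_i = s_i / s_0,      Dcrit = sqrt( F^{-1}(1 - alpha; p - k, n - k - 1) )
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "NipalsPCA",
    "DmodxResult",
    "ConvergenceError",
    "fit_pca",
    "dmodx",
    "r2x_report",
]


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge within the iteration cap."""


@dataclass
class DmodxResult:
    """Per-observation distance to model.

    dmodx : normalized residual standard deviations (>= 0; 0 iff the
    observation lies exactly in the model plane).
    s0 : pooled residual standard deviation of the training set.
    dcrit : critical limit at significance level ``alpha``.
    """

    dmodx: np.ndarray
    s0: float
    dcrit: float
    alpha: float

    def within_limit(self) -> np.ndarray:
        return self.dmodx <= self.dcrit


class NipalsPCA(BaseEstimator, TransformerMixin):
    """Principal component analysis by NIPALS with deflation.

    Mean-centering only by default; unit-variance scaling is available but
    off, because wavelet coefficients of one sequence share a common scale.

    Determinism: the start score vector for each component is the column of
    the (deflated) matrix with the largest variance, and each component's
    sign is fixed so that its largest-magnitude loading entry is positive.

    Attributes (after ``fit``)
    --------------------------
    mean_ : (p,) column means.
    components_ : (k, p) loadings, rows unit-norm and mutually orthogonal.
    scores_ : (n, k) training scores, columns mutually orthogonal.
    explained_variance_ratio_ : (k,) fraction of centered sum of squares
        explained per component (R2X), non-increasing.
    residual_ssq_ : total residual sum of squares after k components.
    total_ssq_ : total centered sum of squares.
    """

    def __init__(
        self,
        n_components: int = 2,
        tol: float = 1e-10,
        max_iter: int = 500,
        scale: bool = False,
    ) -> None:
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.scale = scale

    def fit(self, X, y=None) -> "NipalsPCA":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        n, p = X.shape
        k = self.n_components
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 and p >= 1, got {n}x{p}")
        if k > min(n - 1, p):
            raise ValueError(
                f"n_components={k} exceeds rank bound min(n-1, p) = {min(n - 1, p)}"
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.scale:
            sd = Xc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            self.scale_ = sd
            Xc = Xc / sd
        total_ssq = float(np.sum(Xc**2))
        T = np.zeros((n, k))
        P = np.zeros((p, k))
        R = Xc.copy()
        eps = np.finfo(float).eps
        for a in range(k):
            start = int(np.argmax(R.var(axis=0)))
            t = R[:, start].copy()
            if np.sum(t**2) <= eps * max(total_ssq, 1.0):
                raise ConvergenceError(
                    f"component {a}: deflated matrix has no remaining variance (rank exhausted)"
                )
            converged = False
            for _ in range(self.max_iter):
                pvec = R.T @ t / (t @ t)
                pvec /= np.linalg.norm(pvec)
                t_new = R @ pvec
                if np.linalg.norm(t_new - t) <= self.tol * np.linalg.norm(t_new):
                    t = t_new
                    converged = True
                    break
                t = t_new
            if not converged:
                raise ConvergenceError(
                    f"component {a} did not converge in {self.max_iter} iterations"
                )
            j = int(np.argmax(np.abs(pvec)))
            if pvec[j] < 0:
                pvec, t = -pvec, -t
            T[:, a] = t
            P[:, a] = pvec
            R -= np.outer(t, pvec)
        self.scores_ = T
        self.components_ = P.T
        self.total_ssq_ = total_ssq
        self.residual_ssq_ = float(np.sum(R**2))
        explained = np.sum(T**2, axis=0)
        self.explained_variance_ratio_ = explained / total_ssq if total_ssq > 0 else explained
        self.n_samples_, self.n_features_in_ = n, p
        self.k_ = k
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "components_"):
            raise RuntimeError("model is not fitted")

    def _center(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, dtype=np.float64) - self.mean_
        if self.scale:
            Xc = Xc / self.scale_
        return Xc

    def transform(self, X) -> np.ndarray:
        """Project observations onto the loadings (orthonormal P => the
        least-squares scores are simply X_c P)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {X.shape[1]} columns, model expects {self.n_features_in_}")
        return self._center(X) @ self.components_.T

    def inverse_transform(self, T) -> np.ndarray:
        self._check_fitted()
        rec = np.asarray(T) @ self.components_
        if self.scale:
            rec = rec * self.scale_
        return rec + self.mean_

    def residuals(self, X) -> np.ndarray:
        """E = X_c - T P' for the given observations."""
        self._check_fitted()
        Xc = self._center(np.atleast_2d(np.asarray(X, dtype=np.float64)))
        return Xc - (Xc @ self.components_.T) @ self.components_

    def dmodx(self, X, alpha: float = 0.05) -> DmodxResult:
        """Distance to model for observations ``X`` (see module docstring).

        ``s0`` always refers to the training set; for new observations only
        the per-row residual changes.
        """
        self._check_fitted()
        n, p, k = self.n_samples_, self.n_features_in_, self.k_
        if p <= k:
            raise ValueError(f"DModX undefined for p={p} <= k={k} (no residual dimensions)")
        if n <= k + 1:
            raise ValueError(f"DModX undefined for n={n} <= k+1 (no pooled residual dof)")
        E = self.residuals(X)
        s_i = np.sqrt(np.sum(E**2, axis=1) / (p - k))
        s0 = float(np.sqrt(self.residual_ssq_ / ((n - k - 1) * (p - k))))
        if s0 == 0.0:
            d = np.where(s_i == 0.0, 0.0, np.inf)
        else:
            d = s_i / s0
        dcrit = float(np.sqrt(stats.f.ppf(1.0 - alpha, p - k, n - k - 1)))
        return DmodxResult(dmodx=d, s0=s0, dcrit=dcrit, alpha=alpha)


def fit_pca(
    X: np.ndarray,
    k: int = 2,
    tol: float = 1e-10,
    max_iter: int = 500,
    scale: bool = False,
) -> NipalsPCA:
    """Fit a :class:`NipalsPCA` model with ``k`` components."""
    return NipalsPCA(n_components=k, tol=tol, max_iter=max_iter, scale=scale).fit(X)


def dmodx(model: NipalsPCA, X: np.ndarray, alpha: float = 0.05) -> DmodxResult:
    """Distance to model for ``X`` under a fitted model."""
    return model.dmodx(X, alpha=alpha)


def r2x_report(model: NipalsPCA) -> dict[str, np.ndarray]:
    """Per-component and cumulative explained-variance fractions (R2X)."""
    model._check_fitted()
    r2x = np.asarray(model.explained_variance_ratio_)
    return {"r2x": r2x, "r2x_cum": np.cumsum(r2x)}
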