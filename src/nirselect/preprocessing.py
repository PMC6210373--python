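"""Savitzky-Golay de-noising and Mahalanobis-distance outlier removal.

The SG filter replaces each point by the value of a least-squares
polynomial fitted over a sliding window centred on it (quadratic,
121-point window by default).  Outliers are samples whose Mahalanobis
distance to the mean spectrum exceeds a chi-square-quantile threshold;
by default the distance is computed in a top-25 PC-score representation
because the full-resolution covariance is singular when N << P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter
from scipy.stats import chi2
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import SpectraSet
from .decomposition import SpectralPCA

__all__ = [
    "SavitzkyGolay",
    "MahalanobisOutlierDetector",
    "OutlierReport",
    "sg_smooth",
    "sg_coefficients",
    "mahalanobis_distances",
    "remove_outliers",
]

logger = logging.getLogger(__name__)


def _validate_sg(window: int, poly_order: int, n_points: int | None = None) -> None:
    if window % 2 == 0:
        raise ValueError(f"SG window must be odd, got {window}")
    if window <= poly_order:
        raise ValueError(f"SG window {window} must exceed poly_order {poly_order}")
    if n_points is not None and window > n_points:
        raise ValueError(f"SG window {window} exceeds spectrum length {n_points}")


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """Sliding-window least-squares polynomial smoother (stateless transformer).

    At the boundaries the window polynomial is fitted asymmetrically (a
    polynomial is fitted to the first/last window and evaluated inside it),
    so the output length equals the input length.
    """

    def __init__(self, window: int = 121, poly_order: int = 2):
        self.window = window
        self.poly_order = poly_order

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _validate_sg(self.window, self.poly_order, X.shape[1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _validate_sg(self.window, self.poly_order, X.shape[1])
        return savgol_filter(
            X, self.window, self.poly_order, axis=-1, mode="interp"
        )


def sg_coefficients(window: int = 121, poly_order: int = 2) -> np.ndarray:
    """Convolution coefficients of the interior (centred) SG filter."""
    _validate_sg(window, poly_order)
    return savgol_coeffs(window, poly_order)


def sg_smooth(ds: SpectraSet, window: int = 121, poly_order: int = 2) -> SpectraSet:
    """Smooth every spectrum of a dataset; labels and ids untouched."""
    smoother = SavitzkyGolay(window=window, poly_order=poly_order)
    return ds.with_absorbance(smoother.fit(ds.absorbance).transform(ds.absorbance))


@dataclass
class OutlierReport:
    """Per-sample Mahalanobis distances, the cutoff used and the flagged rows."""

    distances: np.ndarray
    threshold: float
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.flagged = np.asarray(self.flagged, dtype=int)
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")


class MahalanobisOutlierDetector(OutlierMixin, BaseEstimator):
    """Flags samples far from the mean spectrum under the sample covariance.

    Parameters
    ----------
    space : {'pc', 'raw'}, default 'pc'
        Representation in which distances are computed.  'pc' projects onto
        the top `n_components` principal components first (full-rank and
        stable for N << P); 'raw' uses the spectra directly and relies on
        the shrinkage term.
    n_components : int, default 25
        PC count for ``space='pc'`` (capped at N-1).
    shrinkage : float, default 1e-6
        Ridge added to the covariance as ``shrinkage * trace(S)/dim * I``.
    q : float, default 0.999
        Chi-square quantile defining the distance threshold
        ``sqrt(chi2.ppf(q, dim))``.
    pca : fitted SpectralPCA, optional
        Reuse an existing projection instead of fitting one.
    """

    def __init__(
        self,
        space: str = "pc",
        n_components: int = 25,
        shrinkage: float = 1e-6,
        q: float = 0.999,
        pca: SpectralPCA | None = None,
    ):
        self.space = space
        self.n_components = n_components
        self.shrinkage = shrinkage
        self.q = q
        self.pca = pca

    def _represent(self, X: np.ndarray) -> np.ndarray:
        if self.space == "raw":
            return X
        if self.space == "pc":
            return self.pca_.transform(X)
        raise ValueError(f"space must be 'pc' or 'raw', got {self.space!r}")

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, p = X.shape
        if n < 3:
            raise ValueError("need at least 3 samples for a usable covariance")
        if self.space == "pc":
            if self.pca is not None:
                self.pca_ = self.pca
            else:
                k = min(self.n_components, n - 1, p)
                self.pca_ = SpectralPCA(n_components=k).fit(X)
        elif self.space != "raw":
            raise ValueError(f"space must be 'pc' or 'raw', got {self.space!r}")
        z = self._represent(X)
        dim = z.shape[1]
        self.location_ = z.mean(axis=0)
        s = np.cov(z, rowvar=False, ddof=1)
        s = np.atleast_2d(s)
        lam = self.shrinkage * np.trace(s) / dim
        self.covariance_ = s + lam * np.eye(dim)
        self.precision_ = np.linalg.inv(self.covariance_)
        self.threshold_ = float(np.sqrt(chi2.ppf(self.q, dim)))
        self.n_features_in_ = p
        return self

    def mahalanobis(self, X) -> np.ndarray:
        check_is_fitted(self, "precision_")
        z = self._represent(np.atleast_2d(np.asarray(X, dtype=float)))
        d = z - self.location_
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", d, self.precision_, d), 0.0))

    def decision_function(self, X) -> np.ndarray:
        return self.threshold_ - self.mahalanobis(X)

    def predict(self, X) -> np.ndarray:
        """sklearn outlier convention: +1 inlier, -1 outlier."""
        return np.where(self.decision_function(X) >= 0, 1, -1)


def mahalanobis_distances(
    ds: SpectraSet,
    space: str = "pc",
    pca: SpectralPCA | None = None,
    n_components: int = 25,
    shrinkage: float = 1e-6,
) -> OutlierReport:
    """Distance of every spectrum to the mean spectrum (no flagging applied)."""
    det = MahalanobisOutlierDetector(
        space=space, n_components=n_components, shrinkage=shrinkage, pca=pca
    ).fit(ds.absorbance)
    return OutlierReport(distances=det.mahalanobis(ds.absorbance), threshold=np.inf)


def remove_outliers(
    ds: SpectraSet,
    space: str = "pc",
    q: float = 0.999,
    threshold: float | None = None,
    n_components: int = 25,
    shrinkage: float = 1e-6,
    pca: SpectralPCA | None = None,
) -> tuple[SpectraSet, OutlierReport]:
    """Drop samples whose distance exceeds the threshold.

    The cutoff is either given explicitly or taken as the square root of
    the chi-square quantile `q` with as many degrees of freedom as the
    representation has dimensions.  Surviving samples keep their order.
    """
    det = MahalanobisOutlierDetector(
        space=space, n_components=n_components, shrinkage=shrinkage, q=q, pca=pca
    ).fit(ds.absorbance)
    distances = det.mahalanobis(ds.absorbance)
    cut = det.threshold_ if threshold is None else float(threshold)
    flagged = np.flatnonzero(distances > cut)
    if flagged.size == ds.n_samples:
        raise ValueError("outlier policy flagged every sample; nothing retained")
    report = OutlierReport(distances=distances, threshold=cut, flagged=flagged)
    if flagged.size:
        logger.info("removing %d outlier(s): %s", flagged.size, flagged.tolist())
        keep = np.setdiff1d(np.arange(ds.n_samples), flagged)
        return ds.select(keep), report
    return ds, report
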