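"""Mean-centred principal component analysis of spectra.

PCA here is the classical eigendecomposition of the sample covariance
matrix (computed stably through an SVD of the centred data).  Components
are ranked by eigenvalue from large to small; the eigenvalue of a
component, as a fraction of total variance, is the "information" it
carries.  The top 25 components are the default candidate pool for the
downstream genetic feature selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import SpectraSet

__all__ = ["SpectralPCA", "ScoreSet", "fit_pca", "transform_scores", "explained_information"]


class SpectralPCA(TransformerMixin, BaseEstimator):
    """PCA with a deterministic sign convention and full-variance ratios.

    Parameters
    ----------
    n_components : int, default 25
        Number of components to keep; must satisfy
        ``n_components <= min(n_samples - 1, n_points)``.

    Attributes
    ----------
    mean_ : (P,) array
        Per-point mean spectrum subtracted before projection.
    loadings_ : (P, K) array
        Unit-norm eigenvectors of the covariance matrix, columns ordered by
        descending eigenvalue.  The largest-magnitude element of each
        column is made positive so fits are reproducible across platforms.
    eigenvalues_ : (K,) array
        Covariance eigenvalues (1/(N-1) normalisation), descending.
    explained_ratio_ : (K,) array
        ``eigenvalues_ / total_variance_``; over all P components these
        ratios sum to 1, so the stored K sum to <= 1.
    total_variance_ : float
        Sum of variances over all points.
    """

    def __init__(self, n_components: int = 25):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 2:
            raise ValueError("PCA requires at least 2 samples")
        k = self.n_components
        if not 1 <= k <= min(n - 1, p):
            raise ValueError(
                f"n_components={k} must be in [1, min(n_samples-1, n_points)]"
                f" = [1, {min(n - 1, p)}]"
            )
        self.mean_ = X.mean(axis=0)
        xc = X - self.mean_
        _, s, vt = np.linalg.svd(xc, full_matrices=False)
        var = s**2 / (n - 1)
        loadings = vt[:k].T
        # deterministic sign: largest-|.| entry of each loading positive
        flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        self.loadings_ = loadings * flip
        self.eigenvalues_ = var[:k]
        self.total_variance_ = float(var.sum())
        self.explained_ratio_ = (
            self.eigenvalues_ / self.total_variance_
            if self.total_variance_ > 0
            else np.zeros(k)
        )
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean_.size:
            raise ValueError(
                f"X has {X.shape[1]} points, model was fitted with {self.mean_.size}"
            )
        return (X - self.mean_) @ self.loadings_

    def inverse_transform(self, scores) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return scores @ self.loadings_.T + self.mean_

    # -- serialization: JSON for the vectors, CSV for the loading matrix --

    def save(self, prefix) -> None:
        check_is_fitted(self, "loadings_")
        prefix = Path(prefix)
        payload = {
            "n_components": int(self.loadings_.shape[1]),
            "mean": self.mean_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "explained_ratio": self.explained_ratio_.tolist(),
            "total_variance": self.total_variance_,
        }
        prefix.with_suffix(".json").write_text(json.dumps(payload))
        pd.DataFrame(self.loadings_).to_csv(
            prefix.parent / (prefix.name + "-loadings.csv"), index=False
        )

    @classmethod
    def load(cls, prefix) -> "SpectralPCA":
        prefix = Path(prefix)
        payload = json.loads(prefix.with_suffix(".json").read_text())
        model = cls(n_components=payload["n_components"])
        model.mean_ = np.asarray(payload["mean"], dtype=float)
        model.eigenvalues_ = np.asarray(payload["eigenvalues"], dtype=float)
        model.explained_ratio_ = np.asarray(payload["explained_ratio"], dtype=float)
        model.total_variance_ = float(payload["total_variance"])
        model.loadings_ = pd.read_csv(
            prefix.parent / (prefix.name + "-loadings.csv")
        ).to_numpy(dtype=float)
        model.n_features_in_ = model.mean_.size
        return model


@dataclass
class ScoreSet:
    """PC scores of a dataset plus its labels and the model that produced them."""

    scores: np.ndarray
    labels: np.ndarray
    model: SpectralPCA

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def fit_pca(ds: SpectraSet, k: int = 25) -> SpectralPCA:
    """Fit a :class:`SpectralPCA` with `k` components on a dataset."""
    return SpectralPCA(n_components=k).fit(ds.absorbance)


def transform_scores(ds: SpectraSet, model: SpectralPCA) -> ScoreSet:
    """Project a dataset into a fitted model's PC space."""
    return ScoreSet(scores=model.transform(ds.absorbance), labels=ds.labels, model=model)


def explained_information(model: SpectralPCA, mask) -> float:
    """Fraction of total variance carried by the masked components.

    `mask` is a 0/1 (or boolean) vector over the model's stored components.
    Monotone non-decreasing under mask supersets; an all-ones mask over all
    P components would give 1.0.
    """
    check_is_fitted(model, "explained_ratio_")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != model.explained_ratio_.shape:
        raise ValueError(
            f"mask length {mask.size} != number of stored components "
            f"{model.explained_ratio_.size}"
        )
    return float(model.explained_ratio_[mask].sum())
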