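"""Soft-margin RBF-SVM and a binary-decision-tree multiclass scheme.

The two-class classifier is the standard soft-margin SVM: minimise
``1/2 ||w||^2 + C sum(eps_i)`` subject to ``y_i (w.x_i + b) >= 1 - eps_i``,
solved through its dual (box constraints ``0 <= alpha_i <= C`` and the
equality ``sum(alpha_i y_i) = 0``) with the Gaussian RBF kernel
``K(x, y) = exp(-||x - y||^2 / (2 sigma^2))``.

Multiclass problems are handled with an inverted binary tree: each
internal node splits its class set into two groups and trains one binary
SVM to route samples; leaves hold single classes, so a problem with Q
classes uses exactly Q - 1 binary machines.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import _libsvm
from sklearn.utils.validation import check_is_fitted

_libsvm.set_verbosity_wrap(0)

__all__ = [
    "SVMParams",
    "rbf_kernel",
    "BinaryRBFSVM",
    "TreeSVM",
    "ConvergenceError",
    "train_binary",
    "build_tree",
]


class ConvergenceError(RuntimeError):
    """Dual solver stopped before reaching its tolerance."""


@dataclass(frozen=True)
class SVMParams:
    """Hyperparameters of the soft-margin RBF-SVM.

    C is the penalty constant weighting the slack variables; sigma is the
    RBF width.  The study default for both is 2.
    """

    C: float = 2.0
    sigma: float = 2.0

    def __post_init__(self) -> None:
        for name, v in (("C", self.C), ("sigma", self.sigma)):
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")


def rbf_kernel(X, Y=None, sigma: float = 1.0) -> np.ndarray | float:
    """Gaussian similarity ``exp(-||x - y||^2 / (2 sigma^2))``.

    Accepts single vectors (returns a scalar) or matrices (returns the
    Gram/cross-kernel matrix).  Values lie in (0, 1] and the Gram matrix
    is symmetric positive semi-definite.
    """
    if not (np.isfinite(sigma) and sigma > 0):
        raise ValueError(f"sigma must be positive, got {sigma}")
    X = np.asarray(X, dtype=float)
    scalar = X.ndim == 1 and (Y is None or np.asarray(Y).ndim == 1)
    Xm = np.atleast_2d(X)
    Ym = Xm if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    if Xm.shape[1] != Ym.shape[1]:
        raise ValueError(f"dimension mismatch: {Xm.shape[1]} vs {Ym.shape[1]}")
    k = np.exp(-cdist(Xm, Ym, "sqeuclidean") / (2.0 * sigma**2))
    return float(k[0, 0]) if scalar else k


class BinaryRBFSVM(ClassifierMixin, BaseEstimator):
    """Two-class soft-margin SVM with RBF kernel.

    The dual problem is solved by libsvm's SMO; the fitted machine is
    stored explicitly (support vectors, dual coefficients ``alpha_i y_i``
    and bias) and the decision function
    ``g(x) = sum_i alpha_i y_i K(x_i, x) + b`` is evaluated in-package,
    which also makes the model JSON-serializable.

    ``classes_[0]`` maps to the negative side (g <= 0), ``classes_[1]`` to
    the positive side.
    """

    def __init__(self, C: float = 2.0, sigma: float = 2.0, tol: float = 1e-6,
                 max_iter: int = -1):
        self.C = C
        self.sigma = sigma
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        SVMParams(self.C, self.sigma)  # validates
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"binary SVM requires exactly 2 classes, got {self.classes_.size}"
            )
        ybin = np.where(y == self.classes_[1], 1.0, -1.0)
        # low-level libsvm call (the SVC wrapper re-validates inputs on
        # every fit, which dominates runtime at the sizes the GA visits);
        # with labels +/-1 the returned model maps onto sklearn's
        # convention as dual_coef = -coef, intercept = -rho, and the
        # decision function is positive for the +1 class
        support, sv, _, dual, intercept, _, _, fit_status, n_iter = _libsvm.fit(
            np.ascontiguousarray(X),
            ybin,
            svm_type=0,
            kernel="rbf",
            C=float(self.C),
            gamma=1.0 / (2.0 * self.sigma**2),
            tol=float(self.tol),
            max_iter=int(self.max_iter),
        )
        self.n_iter_ = int(np.asarray(n_iter).ravel()[0])
        if fit_status != 0:
            raise ConvergenceError(
                f"dual solver did not converge within {self.n_iter_} iterations"
            )
        self.support_ = np.asarray(support, dtype=int)
        self.support_vectors_ = np.asarray(sv, dtype=float)
        self.dual_coef_ = -np.asarray(dual[0], dtype=float)  # alpha_i * y_i per SV
        self.intercept_ = -float(intercept[0])
        # full-length alpha vector, handy for KKT checks
        self.alpha_ = np.zeros(X.shape[0])
        self.alpha_[self.support_] = np.abs(self.dual_coef_)
        self.y_train_sign_ = ybin
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "support_vectors_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        k = rbf_kernel(X, self.support_vectors_, sigma=self.sigma)
        return k @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def to_dict(self) -> dict:
        check_is_fitted(self, "support_vectors_")
        return {
            "C": self.C,
            "sigma": self.sigma,
            "classes": self.classes_.tolist(),
            "support": self.support_.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BinaryRBFSVM":
        model = cls(C=payload["C"], sigma=payload["sigma"])
        model.classes_ = np.asarray(payload["classes"])
        model.support_ = np.asarray(payload["support"], dtype=int)
        model.support_vectors_ = np.asarray(payload["support_vectors"], dtype=float)
        model.dual_coef_ = np.asarray(payload["dual_coef"], dtype=float)
        model.intercept_ = float(payload["intercept"])
        model.n_features_in_ = model.support_vectors_.shape[1]
        return model


def train_binary(X, y, params: SVMParams = SVMParams()) -> BinaryRBFSVM:
    """Fit a two-class RBF-SVM (thin wrapper over :class:`BinaryRBFSVM`)."""
    return BinaryRBFSVM(C=params.C, sigma=params.sigma).fit(X, y)


@dataclass
class _Node:
    classes: tuple
    # internal nodes
    svm: BinaryRBFSVM | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return len(self.classes) == 1


def _split_ordered(classes: list, class_means: dict) -> tuple[list, list]:
    half = ceil(len(classes) / 2)
    return list(classes[:half]), list(classes[half:])


def _split_centroid(classes: list, class_means: dict) -> tuple[list, list]:
    """Two-means on class-mean vectors, seeded with the two most distant means."""
    mu = np.vstack([class_means[c] for c in classes])
    d = cdist(mu, mu)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    seeds = mu[[i, j]]
    assign = np.argmin(cdist(mu, seeds), axis=1)
    for _ in range(100):
        centers = np.vstack(
            [mu[assign == g].mean(axis=0) if np.any(assign == g) else seeds[g]
             for g in (0, 1)]
        )
        new = np.argmin(cdist(mu, centers), axis=1)
        if np.array_equal(new, assign):
            break
        assign = new
    # guarantee both sides non-empty (ties can collapse a side)
    if np.all(assign == assign[0]):
        assign[i] = 0
        assign[j] = 1
    left = [c for c, g in zip(classes, assign) if g == 0]
    right = [c for c, g in zip(classes, assign) if g == 1]
    return left, right


_SPLIT_POLICIES = {"ordered": _split_ordered, "centroid": _split_centroid}


class TreeSVM(ClassifierMixin, BaseEstimator):
    """Multiclass classifier as an inverted binary tree of RBF-SVMs.

    Parameters
    ----------
    C, sigma : float
        Shared hyperparameters of every node's binary SVM.
    split_policy : {'centroid', 'ordered'}
        How an internal node divides its class set into two groups:
        'centroid' runs a deterministic 2-means on the class-mean vectors
        (seeded with the two most distant means); 'ordered' puts the first
        half of the classes (in sorted label order) on the left.
    """

    def __init__(self, C: float = 2.0, sigma: float = 2.0,
                 split_policy: str = "centroid", tol: float = 1e-6):
        self.C = C
        self.sigma = sigma
        self.split_policy = split_policy
        self.tol = tol

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if self.split_policy not in _SPLIT_POLICIES:
            raise ValueError(f"unknown split_policy {self.split_policy!r}")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        counts = {c: int(np.sum(y == c)) for c in self.classes_}
        empty = [c for c, n in counts.items() if n == 0]
        if empty:
            raise ValueError(f"classes with 0 samples: {empty}")
        class_means = {c: X[y == c].mean(axis=0) for c in self.classes_}
        self.tree_ = self._build(list(self.classes_), X, y, class_means)
        self.n_internal_nodes_ = self.classes_.size - 1
        self.n_features_in_ = X.shape[1]
        return self

    def _build(self, classes: list, X, y, class_means) -> _Node:
        if len(classes) == 1:
            return _Node(classes=tuple(classes))
        left, right = _SPLIT_POLICIES[self.split_policy](classes, class_means)
        ybin = np.where(np.isin(y, right), "R", "L")
        svm = BinaryRBFSVM(C=self.C, sigma=self.sigma, tol=self.tol).fit(X, ybin)
        lmask = np.isin(y, left)
        rmask = np.isin(y, right)
        return _Node(
            classes=tuple(classes),
            svm=svm,
            left=self._build(left, X[lmask], y[lmask], class_means),
            right=self._build(right, X[rmask], y[rmask], class_means),
        )

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        out = np.empty(X.shape[0], dtype=self.classes_.dtype)
        self._route(self.tree_, X, np.arange(X.shape[0]), out)
        return out

    def _route(self, node: _Node, X, idx, out) -> None:
        if node.is_leaf:
            out[idx] = node.classes[0]
            return
        g = node.svm.decision_function(X[idx])
        right = g > 0  # svm trained with "R" as positive class ("L" < "R")
        self._route(node.left, X, idx[~right], out)
        self._route(node.right, X, idx[right], out)

    # -- serialization --

    def to_dict(self) -> dict:
        check_is_fitted(self, "tree_")

        def enc(node: _Node) -> dict:
            if node.is_leaf:
                return {"leaf": node.classes[0]}
            return {
                "classes": list(node.classes),
                "svm": node.svm.to_dict(),
                "left": enc(node.left),
                "right": enc(node.right),
            }

        return {
            "C": self.C,
            "sigma": self.sigma,
            "split_policy": self.split_policy,
            "classes": self.classes_.tolist(),
            "tree": enc(self.tree_),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TreeSVM":
        model = cls(
            C=payload["C"], sigma=payload["sigma"],
            split_policy=payload["split_policy"],
        )

        def dec(d: dict) -> _Node:
            if "leaf" in d:
                return _Node(classes=(d["leaf"],))
            return _Node(
                classes=tuple(d["classes"]),
                svm=BinaryRBFSVM.from_dict(d["svm"]),
                left=dec(d["left"]),
                right=dec(d["right"]),
            )

        model.classes_ = np.asarray(payload["classes"])
        model.tree_ = dec(payload["tree"])
        model.n_internal_nodes_ = model.classes_.size - 1
        model.n_features_in_ = model.tree_.svm.n_features_in_
        return model


def build_tree(X, y, params: SVMParams = SVMParams(),
               split_policy: str = "centroid") -> TreeSVM:
    """Fit a multiclass decision-tree SVM (thin wrapper over :class:`TreeSVM`)."""
    return TreeSVM(C=params.C, sigma=params.sigma, split_policy=split_policy).fit(X, y)
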