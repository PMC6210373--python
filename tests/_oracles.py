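"""Independent brute-force oracles used to cross-check the implementation."""

import itertools

import numpy as np


def svm_dual_bruteforce(K: np.ndarray, y: np.ndarray, C: float):
    """Global minimiser of the SVM dual by active-set enumeration.

    Minimises ``1/2 a^T Q a - 1^T a`` (Q_ij = y_i y_j K_ij) subject to
    ``y^T a = 0`` and ``0 <= a <= C`` by enumerating every assignment of
    each variable to {lower bound, upper bound, free} and solving the
    equality-constrained KKT system on the free set.  Exponential in n;
    intended for n <= 7.

    Returns (objective, alpha).
    """
    n = y.size
    Q = np.outer(y, y) * K
    best_obj, best_a = np.inf, None
    for pattern in itertools.product((0, 1, 2), repeat=n):
        a = np.zeros(n)
        free = [i for i, p in enumerate(pattern) if p == 2]
        upper = [i for i, p in enumerate(pattern) if p == 1]
        a[upper] = C
        if free:
            m = len(free)
            A = np.zeros((m + 1, m + 1))
            A[:m, :m] = Q[np.ix_(free, free)]
            A[:m, m] = y[free]
            A[m, :m] = y[free]
            rhs = np.empty(m + 1)
            rhs[:m] = 1.0 - (Q[np.ix_(free, upper)] @ a[upper] if upper else 0.0)
            rhs[m] = -(y[upper] @ a[upper] if upper else 0.0)
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.linalg.norm(A @ sol - rhs) > 1e-8:
                continue
            a[free] = sol[:m]
            if np.any(a[free] < -1e-10) or np.any(a[free] > C + 1e-10):
                continue
        if abs(y @ a) > 1e-9:
            continue
        obj = 0.5 * a @ Q @ a - a.sum()
        if obj < best_obj:
            best_obj, best_a = obj, a.clip(0.0, C)
    return best_obj, best_a


def dual_objective(K: np.ndarray, y: np.ndarray, alpha: np.ndarray) -> float:
    """Dual objective value ``1/2 a^T Q a - 1^T a`` at a given point."""
    Q = np.outer(y, y) * K
    return float(0.5 * alpha @ Q @ alpha - alpha.sum())


def confusion_tally(y_true, y_pred, label):
    """One-vs-rest confusion counts for a single class by an explicit loop."""
    tp = fn = fp = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == label and p == label:
            tp += 1
        elif t == label:
            fn += 1
        elif p == label:
            fp += 1
        else:
            tn += 1
    return tp, fn, fp, tn


def pca_svd_oracle(X: np.ndarray, k: int):
    """Eigenvalues/loadings of the sample covariance via an SVD of X directly."""
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    return (s**2 / (n - 1))[:k], vt[:k].T
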