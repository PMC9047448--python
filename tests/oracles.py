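"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by a different route than the
package (dense eigendecomposition instead of SVD + generalized eigh,
explicit loops instead of vectorized code) so agreement is evidence, not
tautology.
"""

from __future__ import annotations

import numpy as np


def brute_force_lda(X: np.ndarray, y: np.ndarray, n_keep: int | None = None):
    """Dense Fisher LDA from scratch: eig of inv(Sw) Sb on raw PCA scores.

    Returns (projections, centroids, labels) with directions scaled to unit
    pooled within-class variance, matching the package's convention up to
    per-direction sign.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(set(y))
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    # PCA by eigendecomposition of the covariance matrix (not SVD)
    cov = Xc.T @ Xc
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    k = min(n - 1, p) if n_keep is None else n_keep
    keep = order[:k][evals[order[:k]] > 1e-10 * max(evals.max(), 1.0)]
    P = evecs[:, keep]
    T = Xc @ P

    C = len(classes)
    means = np.vstack([T[y == c].mean(axis=0) for c in classes])
    grand = T.mean(axis=0)
    Sw = np.zeros((T.shape[1],) * 2)
    Sb = np.zeros_like(Sw)
    for ci, c in enumerate(classes):
        for row in T[y == c] - means[ci]:
            Sw += np.outer(row, row)
        diff = means[ci] - grand
        Sb += np.sum(y == c) * np.outer(diff, diff)
    vals, vecs = np.linalg.eig(np.linalg.solve(Sw, Sb))
    vals, vecs = vals.real, vecs.real
    order = np.argsort(vals)[::-1][: min(C - 1, T.shape[1])]
    W = vecs[:, order]
    # unit pooled within-class variance per direction
    for j in range(W.shape[1]):
        w = W[:, j]
        W[:, j] = w / np.sqrt(w @ Sw @ w / (n - C))
    Y = T @ W
    cents = np.vstack([Y[y == c].mean(axis=0) for c in classes])
    dists = np.sqrt(((Y[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2))
    labels = np.array([classes[i] for i in np.argmin(dists, axis=1)], dtype=object)
    return Y, cents, labels


def oneway_anova_f(groups) -> float:
    """Hand-rolled one-way ANOVA F via explicit sums of squares."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    allv = np.concatenate([np.asarray(g, float) for g in groups])
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def align_signs(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Flip B's columns so each correlates positively with A's."""
    B = B.copy()
    for j in range(B.shape[1]):
        if np.dot(A[:, j], B[:, j]) < 0:
            B[:, j] = -B[:, j]
    return B
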