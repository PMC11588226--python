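"""Independent reference implementations used only to check the package.

These deliberately take different algorithmic routes from the library:

* :func:`knn_score_bruteforce` builds the full pairwise distance matrix
  and sums the k smallest off-diagonal entries per row.
* :func:`penalty_simplex_lsq` enforces the sum-to-one constraint with a
  large penalty row on top of non-negative least squares
  (``scipy.optimize.nnls``) — the classical device for constrained
  mixture fits.
* :func:`aa_reference` is an alternating archetype solver built on the
  penalty device, run with many restarts and a tight tolerance, serving
  as a high-effort baseline for the RSS a good fit should reach.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls


def knn_score_bruteforce(points: np.ndarray, k: int) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    D = np.sqrt(
        np.maximum(
            ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1), 0.0
        )
    )
    scores = np.empty(n)
    for i in range(n):
        row = np.delete(D[i], i)
        scores[i] = np.sort(row)[:k].sum()
    return scores


def penalty_simplex_lsq(A: np.ndarray, y: np.ndarray, big: float = 1e6) -> np.ndarray:
    """min ||y - A w||, w >= 0, sum w = 1 via a penalty row and NNLS."""
    m, n = A.shape
    A_aug = np.vstack([A, np.full((1, n), big)])
    y_aug = np.append(y, big)
    w, _ = nnls(A_aug, y_aug, maxiter=10 * n)
    s = w.sum()
    return w / s if s > 0 else np.full(n, 1.0 / n)


def aa_reference(
    X: np.ndarray,
    p: int,
    n_restarts: int = 200,
    max_iter: int = 500,
    tol: float = 1e-10,
    seed: int = 0,
) -> float:
    """Best RSS over many penalty-NNLS alternating fits (Euclidean metric)."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    best = np.inf
    root = np.random.SeedSequence((seed, 777))
    for child in root.spawn(n_restarts):
        rng = np.random.default_rng(child)
        beta = rng.dirichlet(np.ones(n), size=p)
        Z = beta @ X
        prev = np.inf
        for _ in range(max_iter):
            alpha = np.empty((n, p))
            for i in range(n):
                alpha[i] = penalty_simplex_lsq(Z.T, X[i])
            # unconstrained archetype update, then projection into conv(X)
            Ztilde, *_ = np.linalg.lstsq(alpha, X, rcond=None)
            for j in range(p):
                beta[j] = penalty_simplex_lsq(X.T, Ztilde[j])
            Z = beta @ X
            rss = float(((X - alpha @ Z) ** 2).sum())
            if np.isfinite(prev) and abs(prev - rss) <= tol * max(prev, 1e-300):
                break
            prev = rss
        best = min(best, rss)
    return best
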