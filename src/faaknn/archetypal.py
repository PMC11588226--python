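"""Archetype analysis of functional samples in the W-metric.

Archetype analysis (AA) approximates each observation ``x_i`` by a convex
mixture of ``p`` archetypes ``z_j``, each archetype itself a convex
mixture of the observations:

    RSS(alpha, beta) = sum_i || x_i - sum_j alpha_ij z_j ||^2,
    z_j = sum_l beta_jl x_l,

with both ``alpha`` (n x p) and ``beta`` (p x n) row-stochastic.  For
``p > 1`` the archetypes sit on the boundary of the convex hull of the
data, which is exactly the sensitivity to extremes that the outlier
detector exploits.  For functional data the norm is the L2 norm, which
on basis coefficients is the quadratic form of the Gram matrix ``W``; a
symmetric factor ``W = L L'`` maps the problem to ordinary Euclidean AA
on the transformed coefficients ``X L``, so one solver serves grid
values, orthonormal bases and non-orthonormal bases alike.

The optimization alternates exact solves of the two convex subproblems:

* the ``alpha`` step projects every observation onto the convex hull of
  the current archetypes (one small simplex-constrained least-squares
  problem per row, solved exactly by support enumeration);
* the ``beta`` step updates archetypes one at a time.  With the others
  held fixed, the optimal ``beta_j`` solves a single simplex-constrained
  projection of the target ``z_j + (alpha_j' R) / (alpha_j' alpha_j)``
  onto the convex hull of the data (``R`` the current residual matrix) —
  an exact block-coordinate update of the true RSS.

Both steps can only lower the RSS, so within one restart the RSS is
non-increasing by construction.  The objective is non-convex jointly, so
the fit is repeated from random initial ``beta`` matrices (flat Dirichlet
rows) and the best restart wins; ties go to the lowest restart index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from . import _kernels
from ._simplex import simplex_lsq, simplex_lsq_batch
from ._util import check_finite, derive_seed
from .basis import FunctionalSample


@dataclass
class ArchetypalModel:
    """A fitted p-archetype decomposition.

    ``alpha[i, j]`` weights archetype ``j`` in the reconstruction of
    observation ``i``; ``beta[j, l]`` weights observation ``l`` in the
    construction of archetype ``j``; ``Z = beta @ X`` holds the archetype
    coefficients in the original (untransformed) coordinate system.
    ``rss_history`` is the per-alternation RSS trace of the winning
    restart.
    """

    p: int
    alpha: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)
    Z: np.ndarray = field(repr=False)
    rss: float
    converged: bool = True
    iterations: int = 0
    n_restarts_used: int = 1
    seed: int | None = None
    rss_history: list[float] = field(default_factory=list, repr=False)

    def to_json(self, path) -> None:
        payload = {
            "p": self.p,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "Z": self.Z.tolist(),
            "rss": self.rss,
            "converged": self.converged,
            "iterations": self.iterations,
            "n_restarts_used": self.n_restarts_used,
            "seed": self.seed,
            "rss_history": list(self.rss_history),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ArchetypalModel":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("alpha", "beta", "Z"):
            payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


def _coeff_and_transform(X) -> tuple[np.ndarray, np.ndarray]:
    """Return (coefficients, W-metric-transformed coefficients)."""
    if isinstance(X, FunctionalSample):
        B = X.coefficients
        W = X.basis.W
        d = np.diag(W)
        if np.allclose(W, np.diag(d)):
            if np.allclose(d, 1.0):
                return B, B
            return B, B * np.sqrt(d)
        try:
            L = np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            vals, vecs = np.linalg.eigh(W)
            L = vecs * np.sqrt(np.clip(vals, 0.0, None))
        return B, B @ L
    B = check_finite(X, "X")
    if B.ndim != 2:
        raise ValueError("X must be a 2-D matrix or FunctionalSample")
    return B, B


def _fit_single_py(Xt, Gx, beta, max_iter, tol):
    """One restart of the alternating minimization (pure-numpy path).

    Algorithmically identical to the compiled kernel in ``_kernels``;
    kept as the readable reference implementation and as the fallback
    when numba is absent.  ``beta`` is updated in place.
    """
    p = beta.shape[0]
    Z = beta @ Xt
    history: list[float] = []
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # alpha step: project rows onto conv(Z)
        Gz = Z @ Z.T
        Cz = Z @ Xt.T
        alpha = simplex_lsq_batch(Gz, Cz).T
        R = Xt - alpha @ Z
        # beta sweep: exact coordinate update per archetype
        for j in range(p):
            aj = alpha[:, j]
            s = float(aj @ aj)
            if s <= 1e-12:
                # unused archetype: re-seat it at the worst-fit observation
                i_worst = int(np.argmax(np.einsum("ij,ij->i", R, R)))
                beta[j] = 0.0
                beta[j, i_worst] = 1.0
                Z[j] = Xt[i_worst]
                continue
            target = Z[j] + (aj @ R) / s
            w = simplex_lsq(Gx, Xt @ target, w0=beta[j])
            z_new = w @ Xt
            R += np.outer(aj, Z[j] - z_new)
            beta[j] = w
            Z[j] = z_new
        rss = float(np.einsum("ij,ij->", R, R))
        history.append(rss)
        if np.isfinite(prev) and prev - rss <= tol * max(prev, 1e-300):
            converged = True
            break
        prev = rss
    return alpha, history, converged, it


def _fit_single(Xt, Gx, beta, max_iter, tol, use_kernels=_kernels.HAVE_NUMBA):
    if beta.shape[0] > 14:
        use_kernels = False  # numpy path handles large p without enumeration
    if use_kernels:
        alpha, history, it, converged = _kernels.aa_alternate(
            Xt, Gx, beta, max_iter, tol
        )
        return alpha, list(history), converged, it
    return _fit_single_py(Xt, Gx, beta, max_iter, tol)


def fit_archetypes(
    X,
    p: int,
    n_restarts: int = 10,
    max_iter: int = 150,
    tol: float = 1e-6,
    seed: int = 0,
) -> ArchetypalModel:
    """Best-of-restarts archetype analysis.

    Parameters
    ----------
    X : FunctionalSample or (n, m) array
        Input curves; a plain array is treated as Euclidean data (W = I).
    p : number of archetypes, ``1 <= p <= n``.
    n_restarts : random initializations; the lowest-RSS fit is kept.
    max_iter : maximum alternations per restart.
    tol : relative RSS-improvement stopping threshold.
    seed : master seed; restart ``r`` uses a stream derived from
        ``(seed, r)``, so results are reproducible per restart.

    Notes
    -----
    ``p = 1`` has the closed-form solution ``z = column mean`` (the
    unconstrained optimum, which is a convex combination of the data),
    and ``p = n`` is solved by letting every observation be its own
    archetype; both shortcuts are exact.
    """
    B, Xt = _coeff_and_transform(X)
    n = B.shape[0]
    if not 1 <= p <= n:
        raise ValueError(f"invalid p: need 1 <= p <= n={n}, got {p}")
    if p == 1:
        beta = np.full((1, n), 1.0 / n)
        alpha = np.ones((n, 1))
        Rt = Xt - Xt.mean(axis=0, keepdims=True)
        rss = float(np.einsum("ij,ij->", Rt, Rt))
        return ArchetypalModel(1, alpha, beta, beta @ B, rss, True, 0, 0, seed, [rss])
    if p == n:
        eye = np.eye(n)
        return ArchetypalModel(n, eye, eye.copy(), B.copy(), 0.0, True, 0, 0, seed, [0.0])
    Gx = Xt @ Xt.T
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(derive_seed(seed, r))
        beta = rng.dirichlet(np.ones(n), size=p)
        alpha, history, conv, iters = _fit_single(Xt, Gx, beta, max_iter, tol)
        rss = history[-1]
        if best is None or rss < best[2]:
            best = (alpha, beta, rss, history, conv, iters)
    alpha, beta, rss, history, conv, iters = best
    # polish: one exact projection onto the final archetypes, so the stored
    # alpha is exactly the simplex projection a later transform() would
    # compute (and the RSS can only improve)
    Zt = beta @ Xt
    alpha = simplex_lsq_batch(Zt @ Zt.T, Zt @ Xt.T).T
    Rt = Xt - alpha @ Zt
    rss = float(np.einsum("ij,ij->", Rt, Rt))
    history = list(history) + [rss]
    return ArchetypalModel(
        p, alpha, beta, beta @ B, rss, conv, iters, n_restarts, seed, history
    )


def recompute_rss(model: ArchetypalModel, X) -> float:
    """Residual sum of squares of a model on data, in the W-metric."""
    B, Xt = _coeff_and_transform(X)
    Rt = Xt - model.alpha @ model.beta @ Xt
    return float(np.einsum("ij,ij->", Rt, Rt))


def transform(model: ArchetypalModel, X) -> np.ndarray:
    """Mixture weights of new curves on a fitted model's archetypes.

    Solves the simplex-constrained projection of each row of ``X`` onto
    the convex hull of the archetypes; rows of the result are
    non-negative and sum to one.
    """
    B, Xt = _coeff_and_transform(X)
    if model.Z.shape[1] != B.shape[1]:
        raise ValueError(
            f"dimension mismatch: model has {model.Z.shape[1]} coefficients, "
            f"data has {B.shape[1]}"
        )
    if isinstance(X, FunctionalSample):
        # reuse the same metric factor applied to the data
        Zt = _coeff_and_transform(
            FunctionalSample(model.Z, X.basis, grid=X.grid, var_blocks=X.var_blocks)
        )[1]
    else:
        Zt = model.Z
    Gz = Zt @ Zt.T
    Cz = Zt @ Xt.T
    return simplex_lsq_batch(Gz, Cz).T


def rss_curve(
    X,
    p_max: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 150,
    tol: float = 1e-6,
) -> list[tuple[int, float]]:
    """Best-of-restarts RSS for every archetype count ``p = 1..p_max``.

    The per-p seeds are derived from ``(seed, p)`` so extending the range
    never changes already-computed entries.  Archetypes for different
    ``p`` do not nest, so the curve is only softly monotone; use
    :func:`choose_elbow` (or judgement) on the result.
    """
    B = X.coefficients if isinstance(X, FunctionalSample) else np.asarray(X)
    if p_max > B.shape[0]:
        raise ValueError("p_max cannot exceed the number of curves")
    out = []
    for p in range(1, p_max + 1):
        model = fit_archetypes(
            X, p, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            seed=derive_seed(seed, p),
        )
        out.append((p, model.rss))
    return out


def choose_elbow(curve: list[tuple[int, float]]) -> int:
    """Pick the archetype count at the elbow of an RSS curve.

    Returns the interior point with the largest perpendicular distance to
    the chord joining the first and last points of the curve — the usual
    automated reading of "where the RSS starts decreasing at a
    diminishing rate".  Ties break toward the smallest ``p``.  The choice
    is a heuristic; callers can always override it.
    """
    if len(curve) < 3:
        raise ValueError("need at least 3 points to locate an elbow")
    pts = np.asarray(sorted(curve), dtype=float)
    first, last = pts[0], pts[-1]
    chord = last - first
    norm = np.hypot(*chord)
    if norm == 0:
        return int(pts[1, 0])
    inner = pts[1:-1]
    rel = inner - first
    dist = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm
    return int(inner[int(np.argmax(dist)), 0])
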