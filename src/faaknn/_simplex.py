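"""Exact least-squares solvers over the probability simplex.

Both weight matrices in archetype analysis are built from rows that each
solve

    min_w ||y - A w||^2    subject to  w >= 0,  sum_j w_j = 1,

i.e. a least-squares projection onto the convex hull of the columns of
``A``.  The solvers here work from the normal-equation data ``G = A'A``
and ``c = A'y`` (the objective is then ``w'Gw - 2c'w`` up to a constant
that does not depend on ``w``):

* :func:`simplex_lsq_batch` solves many right-hand sides sharing one small
  design — the mixture-weight step, where the design holds the ``p``
  archetypes — by enumerating candidate supports.  The optimum is the
  equality-constrained minimizer restricted to *some* support, and every
  restricted minimizer that happens to be feasible upper-bounds the
  optimum, so the feasible candidate with the smallest objective over all
  ``2^p - 1`` supports is exact.  Cost grows as ``2^p``; ``p`` beyond 14
  is refused.

* :func:`simplex_lsq` solves a single problem in many variables — the
  archetype-weight step, where the design holds all ``n`` observations —
  with a primal active-set method.  It accepts a warm start, which makes
  repeated calls inside an alternating optimization cheap because the
  optimal support rarely changes between sweeps.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np

_MAX_ENUM_P = 14


@lru_cache(maxsize=64)
def _supports(p: int) -> tuple[np.ndarray, ...]:
    """All non-empty supports of {0..p-1}, grouped by size, as index arrays."""
    return tuple(
        np.asarray(list(combinations(range(p), s)), dtype=np.intp)
        for s in range(1, p + 1)
    )


def _restricted_kkt(G, C, S):
    """Solve the equality-constrained normal equations on each support in S.

    S is an (nS, s) array of supports of common size s; returns the stacked
    solutions ``w`` (nS, s, r), multipliers ``lam`` (nS, r) and objectives
    (nS, r).  Singular KKT systems (coincident archetypes) fall back to a
    per-support least-squares solve.
    """
    nS, s = S.shape
    r = C.shape[1]
    K = np.zeros((nS, s + 1, s + 1))
    K[:, :s, :s] = G[S[:, :, None], S[:, None, :]]
    K[:, :s, s] = 1.0
    K[:, s, :s] = 1.0
    CS = C[S]  # (nS, s, r)
    rhs = np.empty((nS, s + 1, r))
    rhs[:, :s, :] = CS
    rhs[:, s, :] = 1.0
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol = np.empty_like(rhs)
        for i in range(nS):
            try:
                sol[i] = np.linalg.solve(K[i], rhs[i])
            except np.linalg.LinAlgError:
                sol[i] = np.linalg.lstsq(K[i], rhs[i], rcond=None)[0]
    w = sol[:, :s, :]
    lam = sol[:, s, :]
    # At a KKT point G_SS w + lam 1 = c_S and 1'w = 1, so
    # w'Gw - 2c'w = -c_S'w - lam.
    obj = -np.einsum("ksr,ksr->kr", CS, w) - lam
    return w, lam, obj


def simplex_lsq_batch(G: np.ndarray, C: np.ndarray, feas_tol: float = 1e-9) -> np.ndarray:
    """Solve ``min_w w'Gw - 2c'w`` on the simplex for every column ``c`` of ``C``.

    Parameters
    ----------
    G : (p, p) Gram matrix of the shared design.
    C : (p, r) matrix whose columns are the per-problem linear terms ``A'y``.

    Returns
    -------
    (p, r) array; each column is the exact minimizer (rows sum to one,
    entries non-negative).
    """
    G = np.asarray(G, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    p, r = C.shape
    if p > _MAX_ENUM_P:
        # enumeration would need 2^p supports; fall back to the exact
        # active-set solver column by column
        return np.column_stack([simplex_lsq(G, C[:, j]) for j in range(r)])
    best_obj = np.full(r, np.inf)
    best = np.zeros((p, r))
    cols = np.arange(r)
    for S in _supports(p):
        w, _, obj = _restricted_kkt(G, C, S)
        s = S.shape[1]
        feas = (
            (w >= -feas_tol).all(axis=1)
            & np.isfinite(obj)
            & (np.abs(w.sum(axis=1) - 1.0) < 1e-6)
        )
        obj = np.where(feas, obj, np.inf)
        k_best = obj.argmin(axis=0)
        val = obj[k_best, cols]
        upd = val < best_obj
        if upd.any():
            best_obj[upd] = val[upd]
            ucols = np.flatnonzero(upd)
            rows = S[k_best[ucols]]  # (nu, s)
            best[:, ucols] = 0.0
            best[rows.T, ucols] = w[k_best[ucols], :, ucols].T
    np.clip(best, 0.0, None, out=best)
    best /= best.sum(axis=0, keepdims=True)
    return best


def _kkt_point(G, c, F):
    """Equality-constrained minimizer on support F; returns (zF, lam)."""
    f = F.size
    K = np.empty((f + 1, f + 1))
    K[:f, :f] = G[np.ix_(F, F)]
    K[:f, f] = 1.0
    K[f, :f] = 1.0
    K[f, f] = 0.0
    rhs = np.empty(f + 1)
    rhs[:f] = c[F]
    rhs[f] = 1.0
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
    return sol[:f], sol[f]


def simplex_lsq(
    G: np.ndarray,
    c: np.ndarray,
    w0: np.ndarray | None = None,
    max_iter: int | None = None,
) -> np.ndarray:
    """Exact single-problem simplex-constrained least squares.

    Primal active-set method on ``min w'Gw - 2c'w`` subject to
    ``w >= 0, 1'w = 1``.  Each iteration solves the equality-constrained
    problem on the current free set; infeasible steps are cut at the
    first variable to hit zero (which then leaves the free set), and at
    a feasible stationary point the bound multipliers of the pinned
    variables are checked to either terminate or release one.  The QP is
    convex, so the method converges to a global optimum from any start;
    a warm start near the optimal (typically small) support makes
    repeated calls inside an alternating scheme cheap.  A warm start
    that already satisfies the KKT conditions returns immediately after
    one matrix-vector product.
    """
    G = np.asarray(G, dtype=float)
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    scale = max(1.0, float(np.abs(G).max()), float(np.abs(c).max()))
    opt_tol = 1e-10 * scale
    if w0 is not None:
        w = np.clip(np.asarray(w0, dtype=float), 0.0, None)
        tot = w.sum()
        if tot > 0:
            w /= tot
            # fast path: is w0 already optimal?  Stationarity requires the
            # reduced gradient to be constant on the support and no smaller
            # off it.
            mu = G @ w - c
            on = w > 1e-12
            lam_lo, lam_hi = mu[on].min(), mu[on].max()
            if lam_hi - lam_lo <= opt_tol and (
                not (~on).any() or mu[~on].min() >= lam_hi - opt_tol
            ):
                return w
            # start from the few dominant warm-start entries
            support = np.flatnonzero(on)
            if support.size > 8:
                support = support[np.argsort(w[support])[-8:]]
            free = np.zeros(n, dtype=bool)
            free[support] = True
            w = np.where(free, w, 0.0)
            w /= w.sum()
        else:
            w0 = None
    if w0 is None:
        j0 = int(np.argmin(np.diag(G) - 2.0 * c))
        w = np.zeros(n)
        w[j0] = 1.0
        free = w > 0
    if max_iter is None:
        max_iter = 5 * n + 100
    for _ in range(max_iter):
        F = np.flatnonzero(free)
        zF, lam = _kkt_point(G, c, F)
        if (zF >= -1e-12).all():
            z = np.zeros(n)
            z[F] = np.clip(zF, 0.0, None)
            tot = z.sum()
            if tot > 0:
                z /= tot
            # bound multipliers for the variables pinned at zero
            mu = G @ z - c + lam
            mu[F] = 0.0
            j = int(np.argmin(mu))
            if mu[j] >= -opt_tol:
                return z
            w = z
            free[j] = True
        else:
            dF = zF - w[F]
            neg = zF < -1e-12
            with np.errstate(divide="ignore", invalid="ignore"):
                steps = np.where(neg, w[F] / np.maximum(w[F] - zF, 1e-300), np.inf)
            jb = int(np.argmin(steps))
            t = min(1.0, max(0.0, steps[jb]))
            w[F] = np.clip(w[F] + t * dF, 0.0, None)
            w[F[jb]] = 0.0
            free[F[jb]] = False
            if not free.any():
                free[int(np.argmin(np.diag(G) - 2.0 * c))] = True
            tot = w.sum()
            if tot > 0:
                w /= tot
    if w0 is not None:
        # iteration guard tripped: keep whichever of (current, warm start)
        # scores better so callers never lose ground
        v = np.clip(np.asarray(w0, dtype=float), 0.0, None)
        v /= v.sum()
        if v @ (G @ v) - 2.0 * (c @ v) < w @ (G @ w) - 2.0 * (c @ w):
            return v
    return w
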