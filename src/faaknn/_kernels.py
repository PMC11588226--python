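"""Compiled inner loops of the alternating archetype solver.

These kernels mirror the pure-numpy algorithm in ``archetypal._fit_single_py``
exactly — the same exact simplex-constrained subproblem solves, the same
sweep order — but run the per-row and per-archetype loops in compiled code
(numba), which removes the Python-call overhead that dominates at the
typical problem size (a hundred curves, a handful of archetypes).

Restricted KKT systems are solved with a tiny Tikhonov term
(``1e-12 * scale``) on the Gram block so they are always non-singular
(coincident archetypes or duplicated curves otherwise produce exactly
singular systems); the perturbation this causes in the subproblem optimum
is orders of magnitude below every tolerance used downstream.

If numba is unavailable the package falls back to the numpy path; both
paths are importable and comparable in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _alpha_step(Gz, Cz, alpha):
    """Exact simplex projection of every row onto conv(archetypes).

    Enumerates the 2^p - 1 candidate supports; for each, solves the
    equality-constrained normal equations once and reuses the factor for
    all n right-hand sides; the feasible candidate with the smallest
    objective is the exact optimum.  Writes the result into ``alpha``
    (n, p) in place.
    """
    p, n = Cz.shape
    scale = 1.0
    for i in range(p):
        for j in range(p):
            a = abs(Gz[i, j])
            if a > scale:
                scale = a
    eps = 1e-12 * scale
    best = np.full(n, np.inf)
    idx = np.empty(p, dtype=np.int64)
    for mask in range(1, 2**p):
        s = 0
        for j in range(p):
            if (mask >> j) & 1:
                idx[s] = j
                s += 1
        K = np.zeros((s + 1, s + 1))
        for a in range(s):
            for b in range(s):
                K[a, b] = Gz[idx[a], idx[b]]
            K[a, a] += eps
            K[a, s] = 1.0
            K[s, a] = 1.0
        rhs = np.empty((s + 1, n))
        for a in range(s):
            for col in range(n):
                rhs[a, col] = Cz[idx[a], col]
        for col in range(n):
            rhs[s, col] = 1.0
        sol = np.linalg.solve(K, rhs)
        for col in range(n):
            feas = True
            obj = -sol[s, col]
            for a in range(s):
                w = sol[a, col]
                if w < -1e-9:
                    feas = False
                    break
                obj -= Cz[idx[a], col] * w
            if feas and obj < best[col]:
                best[col] = obj
                for j in range(p):
                    alpha[col, j] = 0.0
                tot = 0.0
                for a in range(s):
                    w = sol[a, col]
                    if w < 0.0:
                        w = 0.0
                    alpha[col, idx[a]] = w
                    tot += w
                for a in range(s):
                    alpha[col, idx[a]] /= tot


@njit(cache=True)
def _simplex_single(G, c, w):
    """Exact active-set solve of min w'Gw - 2c'w on the simplex, in place.

    ``w`` enters as a feasible warm start and leaves as the optimum.
    Identical strategy to the numpy implementation: KKT solve on the free
    set, blocking-step removal of variables driven negative, and release
    of the most negative bound multiplier at stationary points.
    """
    n = c.shape[0]
    scale = 1.0
    for i in range(n):
        a = abs(c[i])
        if a > scale:
            scale = a
        for j in range(n):
            a = abs(G[i, j])
            if a > scale:
                scale = a
    opt_tol = 1e-10 * scale
    eps = 1e-12 * scale

    # fast path: warm start already stationary
    mu = G @ w - c
    lam_lo = np.inf
    lam_hi = -np.inf
    for i in range(n):
        if w[i] > 1e-12:
            if mu[i] < lam_lo:
                lam_lo = mu[i]
            if mu[i] > lam_hi:
                lam_hi = mu[i]
    if lam_hi - lam_lo <= opt_tol:
        ok = True
        for i in range(n):
            if w[i] <= 1e-12 and mu[i] < lam_hi - opt_tol:
                ok = False
                break
        if ok:
            return

    free = np.zeros(n, dtype=np.bool_)
    # dominant warm-start entries as the initial free set (at most 8)
    nz = 0
    for i in range(n):
        if w[i] > 1e-12:
            nz += 1
    if nz == 0:
        jbest = 0
        vbest = np.inf
        for j in range(n):
            v = G[j, j] - 2.0 * c[j]
            if v < vbest:
                vbest = v
                jbest = j
        for i in range(n):
            w[i] = 0.0
        w[jbest] = 1.0
        free[jbest] = True
    elif nz <= 8:
        for i in range(n):
            free[i] = w[i] > 1e-12
    else:
        order = np.argsort(w)
        for q in range(n - 8, n):
            free[order[q]] = True
        tot = 0.0
        for i in range(n):
            if not free[i]:
                w[i] = 0.0
            tot += w[i]
        for i in range(n):
            w[i] /= tot

    max_iter = 5 * n + 100
    for _ in range(max_iter):
        f = 0
        for i in range(n):
            if free[i]:
                f += 1
        F = np.empty(f, dtype=np.int64)
        q = 0
        for i in range(n):
            if free[i]:
                F[q] = i
                q += 1
        K = np.zeros((f + 1, f + 1))
        rhs = np.empty(f + 1)
        for a in range(f):
            for b in range(f):
                K[a, b] = G[F[a], F[b]]
            K[a, a] += eps
            K[a, f] = 1.0
            K[f, a] = 1.0
            rhs[a] = c[F[a]]
        rhs[f] = 1.0
        sol = np.linalg.solve(K, rhs)
        lam = sol[f]
        all_nonneg = True
        for a in range(f):
            if sol[a] < -1e-12:
                all_nonneg = False
                break
        if all_nonneg:
            tot = 0.0
            for i in range(n):
                w[i] = 0.0
            for a in range(f):
                v = sol[a]
                if v < 0.0:
                    v = 0.0
                w[F[a]] = v
                tot += v
            for i in range(n):
                w[i] /= tot
            mu = G @ w - c
            jworst = -1
            vworst = -opt_tol
            for j in range(n):
                if not free[j] and mu[j] + lam < vworst:
                    vworst = mu[j] + lam
                    jworst = j
            if jworst < 0:
                return
            free[jworst] = True
        else:
            t = 1.0
            jb = -1
            for a in range(f):
                if sol[a] < -1e-12:
                    denom = w[F[a]] - sol[a]
                    step = w[F[a]] / denom if denom > 1e-300 else 0.0
                    if step < t:
                        t = step
                        jb = a
            tot = 0.0
            for a in range(f):
                v = w[F[a]] + t * (sol[a] - w[F[a]])
                if v < 0.0:
                    v = 0.0
                w[F[a]] = v
            if jb >= 0:
                w[F[jb]] = 0.0
                free[F[jb]] = False
            any_free = False
            for i in range(n):
                if free[i]:
                    any_free = True
                    break
            if not any_free:
                jbest = 0
                vbest = np.inf
                for j in range(n):
                    v = G[j, j] - 2.0 * c[j]
                    if v < vbest:
                        vbest = v
                        jbest = j
                free[jbest] = True
            for i in range(n):
                tot += w[i]
            if tot > 0.0:
                for i in range(n):
                    w[i] /= tot


@njit(cache=True)
def aa_alternate(Xt, Gx, beta, max_iter, tol):
    """Full alternating minimization from a given initial beta.

    Returns (alpha, rss_history, n_iters, converged); ``beta`` is
    updated in place.  The RSS trace is recorded once per full
    alternation (alpha step plus beta sweep) and is non-increasing by
    construction, since every substep is an exact solve of its convex
    subproblem.
    """
    p = beta.shape[0]
    n, m = Xt.shape
    Z = beta @ Xt
    alpha = np.full((n, p), 1.0 / p)
    history = np.empty(max_iter)
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Gz = Z @ Z.T
        Cz = Z @ Xt.T
        _alpha_step(Gz, Cz, alpha)
        R = Xt - alpha @ Z
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += alpha[i, j] * alpha[i, j]
            if s <= 1e-12:
                # unused archetype: re-seat at the worst-fit observation
                iworst = 0
                vworst = -1.0
                for i in range(n):
                    v = 0.0
                    for h in range(m):
                        v += R[i, h] * R[i, h]
                    if v > vworst:
                        vworst = v
                        iworst = i
                for l in range(n):
                    beta[j, l] = 0.0
                beta[j, iworst] = 1.0
                for h in range(m):
                    Z[j, h] = Xt[iworst, h]
                continue
            target = np.empty(m)
            for h in range(m):
                acc = 0.0
                for i in range(n):
                    acc += alpha[i, j] * R[i, h]
                target[h] = Z[j, h] + acc / s
            ct = Xt @ target
            _simplex_single(Gx, ct, beta[j])
            znew = beta[j] @ Xt
            for i in range(n):
                aij = alpha[i, j]
                for h in range(m):
                    R[i, h] += aij * (Z[j, h] - znew[h])
            for h in range(m):
                Z[j, h] = znew[h]
        rss = 0.0
        for i in range(n):
            for h in range(m):
                rss += R[i, h] * R[i, h]
        history[it - 1] = rss
        if np.isfinite(prev) and prev - rss <= tol * prev:
            converged = True
            break
        prev = rss
    return alpha, history[:it], it, converged
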