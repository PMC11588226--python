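"""Functional samples, basis systems and the inner-product Gram matrix.

A curve ``x(t)`` on an interval ``[a, b]`` is represented either by its
values on a common observation grid (the ``discrete`` family) or by the
coefficients of a basis expansion ``x(t) = sum_h b_h B_h(t)`` (``fourier``
or ``bspline``).  All downstream computations measure residuals in the L2
norm, which on coefficients becomes the quadratic form ``a' W a`` with
``W`` the Gram matrix of basis inner products ``W_hk = ∫ B_h B_k``.  For
an orthonormal basis (Fourier) ``W`` is the identity; for grid values it
is ``h·I`` with ``h`` the grid spacing, i.e. a Riemann approximation of
the integral, so residual norms stay comparable across grid resolutions.

Multivariate curves (several functional variables observed together) are
handled by stacking the per-variable coefficient matrices column-wise;
the stacked metric is the block-diagonal of the per-variable ``W``s, so
the squared norm of a stacked residual is the sum of the per-variable
squared norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline
from scipy.linalg import block_diag

from ._util import check_finite

FAMILIES = ("discrete", "fourier", "bspline")


@dataclass(frozen=True)
class BasisSystem:
    """A basis family on a domain, with its inner-product Gram matrix.

    Attributes
    ----------
    family : one of ``discrete``, ``fourier``, ``bspline``.
    m : number of basis functions (grid points for ``discrete``).
    domain : the interval ``(a, b)``.
    W : (m, m) Gram matrix of pairwise basis inner products.
    grid : the observation grid (``discrete`` family only).
    degree : spline degree (``bspline`` family only).
    knots : full knot vector (``bspline`` family only).
    """

    family: str
    m: int
    domain: tuple[float, float]
    W: np.ndarray = field(repr=False)
    grid: np.ndarray | None = field(default=None, repr=False)
    degree: int | None = None
    knots: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown basis family {self.family!r}")
        a, b = self.domain
        if not a < b:
            raise ValueError(f"invalid domain: need a < b, got [{a}, {b}]")
        W = np.asarray(self.W, dtype=float)
        if W.shape != (self.m, self.m):
            raise ValueError("W must be m x m")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("W must be symmetric")
        object.__setattr__(self, "W", W)

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at ``grid``; returns (g, m)."""
        grid = np.asarray(grid, dtype=float)
        a, b = self.domain
        if grid.min() < a - 1e-12 or grid.max() > b + 1e-12:
            raise ValueError("evaluation grid outside basis domain")
        if self.family == "fourier":
            return _fourier_design(grid, self.m, a, b)
        if self.family == "bspline":
            return BSpline.design_matrix(
                np.clip(grid, a, b), self.knots, self.degree
            ).toarray()
        raise ValueError("discrete basis has no continuous evaluation")

    def compatible_with(self, other: "BasisSystem") -> bool:
        return (
            self.family == other.family
            and self.m == other.m
            and np.allclose(self.domain, other.domain)
            and np.allclose(self.W, other.W)
        )


@dataclass
class FunctionalSample:
    """``n`` curves as an (n, m) coefficient matrix plus its basis.

    For the ``discrete`` family the "coefficients" are the raw grid
    values.  ``var_blocks`` delimits the column range of each stacked
    functional variable; univariate samples have the single block
    ``(0, m)``.
    """

    coefficients: np.ndarray
    basis: BasisSystem
    grid: np.ndarray | None = None
    n_vars: int = 1
    var_blocks: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        self.coefficients = check_finite(self.coefficients, "coefficients")
        if self.coefficients.ndim != 2:
            raise ValueError("coefficients must be a 2-D matrix")
        m = self.coefficients.shape[1]
        if self.var_blocks is None:
            self.var_blocks = ((0, m),)
        widths = [b - a for a, b in self.var_blocks]
        if any(w <= 0 for w in widths):
            raise ValueError("every variable block must have positive width")
        if sum(widths) != m:
            raise ValueError("variable blocks must tile the coefficient columns")
        self.n_vars = len(self.var_blocks)
        if self.basis.family == "discrete":
            if self.grid is None:
                self.grid = self.basis.grid
            g = np.asarray(self.grid, dtype=float)
            if g is None or np.any(np.diff(g) <= 0):
                raise ValueError("discrete samples need a strictly increasing grid")
            a, b = self.basis.domain
            if g.min() < a - 1e-12 or g.max() > b + 1e-12:
                raise ValueError("grid outside basis domain")
            self.grid = g

    @property
    def n(self) -> int:
        return self.coefficients.shape[0]

    @property
    def m(self) -> int:
        return self.coefficients.shape[1]

    def block(self, i: int) -> "FunctionalSample":
        """Extract the i-th stacked variable as its own sample."""
        a, b = self.var_blocks[i]
        W = self.basis.W[a:b, a:b]
        basis = replace(self.basis, m=b - a, W=W)
        return FunctionalSample(self.coefficients[:, a:b].copy(), basis, grid=self.grid)


def make_discrete_basis(n_points: int, a: float, b: float) -> BasisSystem:
    """Grid-value "basis": curves are their values at equispaced points.

    The Gram matrix is ``h·I`` with ``h = (b-a)/(n_points-1)``, the Riemann
    weight of the grid, so coefficient-space quadratic forms approximate
    the L2 integral.
    """
    if n_points < 2:
        raise ValueError(f"invalid size: need at least 2 grid points, got {n_points}")
    if not a < b:
        raise ValueError(f"invalid domain: need a < b, got [{a}, {b}]")
    h = (b - a) / (n_points - 1)
    grid = np.linspace(a, b, n_points)
    return BasisSystem("discrete", n_points, (float(a), float(b)), h * np.eye(n_points), grid=grid)


def make_fourier_basis(m: int, a: float, b: float) -> BasisSystem:
    """Orthonormal Fourier basis (constant, then sin/cos pairs) on [a, b]."""
    if m < 1:
        raise ValueError("invalid size: m must be >= 1")
    if not a < b:
        raise ValueError(f"invalid domain: need a < b, got [{a}, {b}]")
    return BasisSystem("fourier", m, (float(a), float(b)), np.eye(m))


def make_bspline_basis(m: int, a: float, b: float, degree: int = 3) -> BasisSystem:
    """B-spline basis of the given degree with equispaced knots on [a, b]."""
    if not a < b:
        raise ValueError(f"invalid domain: need a < b, got [{a}, {b}]")
    if m < degree + 1:
        raise ValueError(f"invalid size: need m >= degree+1 = {degree + 1}")
    inner = np.linspace(a, b, m - degree + 1)
    knots = np.concatenate([np.full(degree, a), inner, np.full(degree, b)])
    basis = BasisSystem(
        "bspline", m, (float(a), float(b)), np.eye(m), degree=degree, knots=knots
    )
    W = _bspline_gram(basis)
    return replace(basis, W=W)


def _fourier_design(grid: np.ndarray, m: int, a: float, b: float) -> np.ndarray:
    period = b - a
    u = (grid - a) / period
    E = np.empty((grid.size, m))
    E[:, 0] = 1.0 / np.sqrt(period)
    amp = np.sqrt(2.0 / period)
    for h in range(1, m):
        r = (h + 1) // 2
        phase = 2.0 * np.pi * r * u
        E[:, h] = amp * (np.sin(phase) if h % 2 == 1 else np.cos(phase))
    return E


def _bspline_gram(basis: BasisSystem, nodes_per_span: int = 8) -> np.ndarray:
    """Gram matrix by Gauss-Legendre quadrature, exact per polynomial span."""
    x, w = leggauss(nodes_per_span)
    spans = np.unique(basis.knots)
    pts, wts = [], []
    for lo, hi in zip(spans[:-1], spans[1:]):
        half = (hi - lo) / 2.0
        pts.append(half * x + (hi + lo) / 2.0)
        wts.append(half * w)
    pts = np.concatenate(pts)
    wts = np.concatenate(wts)
    E = basis.evaluate(pts)
    return (E * wts[:, None]).T @ E


def gram_matrix(basis: BasisSystem) -> np.ndarray:
    """(Re)compute the inner-product Gram matrix of a basis system.

    Identity for Fourier (orthonormal), ``h·I`` for the discrete family,
    and fixed-order Gauss-Legendre quadrature per knot span for B-splines
    (exact, since the integrands are piecewise polynomials).
    """
    if basis.family == "fourier":
        return np.eye(basis.m)
    if basis.family == "discrete":
        a, b = basis.domain
        return (b - a) / (basis.m - 1) * np.eye(basis.m)
    return _bspline_gram(basis)


def fit_coefficients(
    values: np.ndarray, grid: np.ndarray, basis: BasisSystem
) -> FunctionalSample:
    """Least-squares basis expansion of raw curve observations.

    Each row of ``values`` (curves observed at ``grid``) is projected onto
    the basis evaluated at the same grid.  The discrete family passes the
    values through unchanged (the grid must match the basis grid).
    """
    values = check_finite(values, "values")
    grid = np.asarray(grid, dtype=float)
    if values.shape[1] != grid.size:
        raise ValueError("values and grid lengths differ")
    if basis.family == "discrete":
        if basis.grid.size != grid.size or not np.allclose(basis.grid, grid):
            raise ValueError("discrete family requires the basis grid")
        return FunctionalSample(values.copy(), basis, grid=grid)
    if grid.size < basis.m:
        raise ValueError("need at least as many grid points as basis functions")
    E = basis.evaluate(grid)
    coef, _, rank, _ = np.linalg.lstsq(E, values.T, rcond=None)
    if rank < basis.m:
        raise ValueError(
            f"rank-deficient basis evaluation (rank {rank} < m={basis.m}); "
            "use a denser grid or fewer basis functions"
        )
    return FunctionalSample(coef.T, basis)


def evaluate_sample(sample: FunctionalSample, grid: np.ndarray) -> np.ndarray:
    """Reconstruct curve values at ``grid`` from a (univariate) sample."""
    if sample.n_vars != 1:
        raise ValueError("evaluate one variable block at a time")
    if sample.basis.family == "discrete":
        if not np.allclose(grid, sample.grid):
            raise ValueError("discrete samples evaluate only on their own grid")
        return sample.coefficients.copy()
    return sample.coefficients @ sample.basis.evaluate(np.asarray(grid, float)).T


def stack_multivariate(
    samples: list[FunctionalSample], standardize: bool = False
) -> FunctionalSample:
    """Join per-variable samples column-wise into one multivariate sample.

    All samples must share the number of curves and the basis family; the
    stacked metric is block-diagonal, so the L2 norm of a multivariate
    residual decomposes as the sum over variables.  With ``standardize``
    each variable block is centred (column means) and divided by its
    pooled centred W-norm, which puts variables with different ranges on
    a common scale before a joint decomposition.
    """
    if not samples:
        raise ValueError("need at least one sample")
    if len(samples) == 1:
        return samples[0]
    n = samples[0].n
    fam = samples[0].basis.family
    for s in samples[1:]:
        if s.n != n:
            raise ValueError("all samples must contain the same number of curves")
        if s.basis.family != fam or not np.allclose(s.basis.domain, samples[0].basis.domain):
            raise ValueError("incompatible bases across variables")
        if fam == "discrete" and not np.allclose(s.grid, samples[0].grid):
            raise ValueError("discrete variables must share the observation grid")
    blocks, mats = [], []
    offset = 0
    for s in samples:
        X = s.coefficients
        if standardize:
            X = X - X.mean(axis=0, keepdims=True)
            sq = np.einsum("ij,jk,ik->i", X, s.basis.W, X)
            scale = np.sqrt(max(sq.mean(), 1e-300))
            X = X / scale
        mats.append(X)
        blocks.append((offset, offset + s.m))
        offset += s.m
    W = block_diag(*[s.basis.W for s in samples])
    basis = BasisSystem(fam, offset, samples[0].basis.domain, W,
                        grid=samples[0].grid if fam == "discrete" else None)
    return FunctionalSample(
        np.hstack(mats), basis,
        grid=samples[0].grid if fam == "discrete" else None,
        var_blocks=tuple(blocks),
    )
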