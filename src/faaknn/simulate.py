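"""Synthetic clustered functional data with planted outliers.

The generator reproduces a standard simulation design for functional
outlier detection.  All curves are observed at ``grid_size`` equidistant
points in [0, 1] and share the noise model: a zero-mean Gaussian process
with exponential covariance

    gamma(s, t) = 0.3 * exp(-|s - t| / 0.3),

i.e. pointwise variance 0.3 and correlation length 0.3.  The bulk of the
data follows the noisy hump

    X1(t) = 30 t (1 - t)^{3/2} + eps(t),

("cluster 1"); a second cluster and five outlier families are built from
it:

====================  ==========================  ==========================
outlier family        outliers (5 curves)         cluster 2 (25 curves)
====================  ==========================  ==========================
amplitude             3 * X1(t)                   6 * X1(t)
vertical shift        3 + X1(t)                   6 + X1(t)
horizontal shift      X1(t + 0.15)                X1(t + 0.3)
shape                 15 t^2 (1-t)^2 + eps(t)     10 t^{1/3} (1-t)^3 + eps(t)
isolated              X1(t) + 15 Z1               X1(t) + 15 Z2
====================  ==========================  ==========================

``Z1``/``Z2`` are truncated standard normal density bumps supported on
the first / last 11 grid points (centered on the 6th and 20th
observations, 1-based).  Every family perturbs the *mean* structure and
adds the common GP noise unscaled: the amplitude factors 3 and 6
multiply the mean hump, the vertical shifts add a constant, and the
horizontal shifts evaluate the X1 mean at ``t + delta`` (continued by
zero past t = 1, where the mean vanishes) with noise on the observation
grid.  Keeping the noise scale common across groups makes every family
a perturbation of location/shape rather than of dispersion; a shared
underlying noise realization per group links the families of one seed
bit for bit.

The one-cluster scenario has 95 cluster-1 curves + 5 outliers; the
two-cluster scenario has 70 + 25 + 5.  Row order is cluster 1, then
cluster 2, then the outliers; ``cluster_ids`` uses 0 for outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ._util import derive_seed
from .basis import FunctionalSample, make_discrete_basis

GP_VARIANCE = 0.3
GP_LENGTHSCALE = 0.3

OUTLIER_TYPES = ("amplitude", "v_shift", "h_shift", "shape", "isolated")
SCENARIOS = ("one_cluster", "two_cluster")


@dataclass(frozen=True)
class ScenarioConfig:
    """Composition of one synthetic dataset."""

    scenario: str
    outlier_type: str
    n_total: int = 100
    n_outliers: int = 5
    grid_size: int = 25
    seed: int = 0
    cluster_sizes: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.outlier_type not in OUTLIER_TYPES:
            raise ValueError(f"unknown outlier type {self.outlier_type!r}")
        if self.cluster_sizes is None:
            if self.scenario == "one_cluster":
                sizes = (self.n_total - self.n_outliers,)
            else:
                n2 = round(self.n_total / 4)
                sizes = (self.n_total - self.n_outliers - n2, n2)
            object.__setattr__(self, "cluster_sizes", sizes)
        want = 1 if self.scenario == "one_cluster" else 2
        if len(self.cluster_sizes) != want:
            raise ValueError(f"{self.scenario} needs {want} cluster size(s)")
        if sum(self.cluster_sizes) + self.n_outliers != self.n_total:
            raise ValueError(
                "cluster sizes plus outliers must sum to n_total "
                f"({self.cluster_sizes} + {self.n_outliers} != {self.n_total})"
            )
        if any(s < 1 for s in self.cluster_sizes) or self.n_outliers < 1:
            raise ValueError("all group sizes must be positive")


@dataclass
class LabeledSample:
    """A generated sample with ground truth.

    ``labels`` is True exactly for the planted outliers;
    ``cluster_ids`` is 0 for outliers and 1, 2, ... for the clusters.
    """

    sample: FunctionalSample
    labels: np.ndarray
    cluster_ids: np.ndarray
    config: ScenarioConfig | None = field(default=None, repr=False)

    def __post_init__(self):
        if not np.array_equal(self.labels, self.cluster_ids == 0):
            raise ValueError("labels must mark exactly the cluster_ids == 0 rows")


def exp_cov_matrix(grid: np.ndarray) -> np.ndarray:
    """Exponential GP covariance 0.3·exp(−|s−t|/0.3) on a grid."""
    grid = np.asarray(grid, dtype=float)
    return GP_VARIANCE * np.exp(-np.abs(grid[:, None] - grid[None, :]) / GP_LENGTHSCALE)


def sample_gp_noise(n: int, grid: np.ndarray, seed) -> np.ndarray:
    """Independent draws of the zero-mean exponential-covariance GP.

    Realized by applying the symmetric matrix square root of the
    covariance (eigendecomposition, negative eigenvalues clipped at
    zero) to i.i.d. standard normal vectors.  ``seed`` may be an int or
    a ``numpy.random.Generator``.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = exp_cov_matrix(grid)
    vals, vecs = np.linalg.eigh(C)
    root = (vecs * np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    return rng.standard_normal((n, grid.size)) @ root


def mean_cluster1(t) -> np.ndarray:
    """The cluster-1 mean 30·t·(1−t)^{3/2}, continued by zero for t > 1.

    The zero continuation is the continuous extension (the mean vanishes
    at t = 1 and (1−t)^{3/2} is undefined beyond it); it is what the
    horizontally shifted families evaluate at t + 0.15 and t + 0.3.
    """
    t = np.asarray(t, dtype=float)
    u = np.clip(1.0 - t, 0.0, None)
    return 30.0 * t * u ** 1.5


def mean_shape_outlier(t) -> np.ndarray:
    """Alternative mean of the shape-outlier family, 15·t²·(1−t)²."""
    t = np.asarray(t, dtype=float)
    return 15.0 * t**2 * (1.0 - t) ** 2


def mean_shape_cluster2(t) -> np.ndarray:
    """Alternative mean of the shape second cluster, 10·t^{1/3}·(1−t)³."""
    t = np.asarray(t, dtype=float)
    return 10.0 * np.cbrt(t) * (1.0 - t) ** 3


def normal_bump(
    center_index_1based: int, half_window: int = 5, grid_size: int = 25
) -> np.ndarray:
    """A truncated standard-normal density bump on part of the grid.

    Zero outside a ``2·half_window + 1``-point window centred on the
    given (1-based) observation index; inside, the standard normal
    density evaluated at equally spaced arguments spanning [−3, 3].
    """
    c = center_index_1based - 1
    lo, hi = c - half_window, c + half_window
    if lo < 0 or hi >= grid_size:
        raise ValueError(
            f"bump window [{lo}, {hi}] does not fit in a {grid_size}-point grid"
        )
    out = np.zeros(grid_size)
    out[lo : hi + 1] = norm.pdf(np.linspace(-3.0, 3.0, 2 * half_window + 1))
    return out


def group_mean_curves(config: ScenarioConfig) -> dict[str, np.ndarray]:
    """Noise-free mean curves of each group, keyed 'cluster1'/'cluster2'/'outlier'.

    For the amplitude and shift families these are the transformed
    cluster-1 mean (the noise has mean zero, so transforming a noisy
    realization transforms the mean identically).
    """
    grid = np.linspace(0.0, 1.0, config.grid_size)
    mu1 = mean_cluster1(grid)
    kind = config.outlier_type
    if kind == "amplitude":
        out, c2 = 3.0 * mu1, 6.0 * mu1
    elif kind == "v_shift":
        out, c2 = 3.0 + mu1, 6.0 + mu1
    elif kind == "h_shift":
        out, c2 = mean_cluster1(grid + 0.15), mean_cluster1(grid + 0.3)
    elif kind == "shape":
        out, c2 = mean_shape_outlier(grid), mean_shape_cluster2(grid)
    else:  # isolated
        out = mu1 + 15.0 * normal_bump(6, grid_size=config.grid_size)
        c2 = mu1 + 15.0 * normal_bump(20, grid_size=config.grid_size)
    means = {"cluster1": mu1, "outlier": out}
    if config.scenario == "two_cluster":
        means["cluster2"] = c2
    return means


def _group_curves(kind: str, role: str, grid, noise) -> np.ndarray:
    """Curves of one group given its pre-drawn GP noise matrix.

    ``role`` is 'outlier' or 'cluster2'; cluster 1 is always mu1 + noise.
    The base realization X1 = mu1 + noise is reused so that, e.g., the
    amplitude and vertical-shift transforms of the same seed share their
    noise paths bit for bit.
    """
    mu1 = mean_cluster1(grid)
    base = mu1 + noise
    delta = 0.15 if role == "outlier" else 0.3
    if kind == "amplitude":
        # the amplitude factor scales the underlying mean; the additive GP
        # noise keeps the common scale, as in the other families
        return (3.0 if role == "outlier" else 6.0) * mu1 + noise
    if kind == "v_shift":
        return (3.0 if role == "outlier" else 6.0) + base
    if kind == "h_shift":
        return mean_cluster1(grid + delta) + noise
    if kind == "shape":
        mean = mean_shape_outlier(grid) if role == "outlier" else mean_shape_cluster2(grid)
        return mean + noise
    bump = normal_bump(6 if role == "outlier" else 20, grid_size=grid.size)
    return base + 15.0 * bump


def build_scenario(config: ScenarioConfig) -> LabeledSample:
    """Generate one labeled dataset according to the scenario design."""
    grid = np.linspace(0.0, 1.0, config.grid_size)
    mu1 = mean_cluster1(grid)
    # one independent noise stream per group, independent of outlier type
    rng_c1 = np.random.default_rng(derive_seed(config.seed, 1))
    rng_c2 = np.random.default_rng(derive_seed(config.seed, 2))
    rng_out = np.random.default_rng(derive_seed(config.seed, 3))

    parts, ids = [], []
    n1 = config.cluster_sizes[0]
    parts.append(mu1 + sample_gp_noise(n1, grid, rng_c1))
    ids.append(np.full(n1, 1))
    if config.scenario == "two_cluster":
        n2 = config.cluster_sizes[1]
        noise2 = sample_gp_noise(n2, grid, rng_c2)
        parts.append(_group_curves(config.outlier_type, "cluster2", grid, noise2))
        ids.append(np.full(n2, 2))
    noise_out = sample_gp_noise(config.n_outliers, grid, rng_out)
    parts.append(_group_curves(config.outlier_type, "outlier", grid, noise_out))
    ids.append(np.zeros(config.n_outliers, dtype=int))

    values = np.vstack(parts)
    cluster_ids = np.concatenate(ids)
    basis = make_discrete_basis(config.grid_size, 0.0, 1.0)
    sample = FunctionalSample(values, basis, grid=grid)
    return LabeledSample(sample, cluster_ids == 0, cluster_ids, config)


def build_toy_multicluster(seed: int = 0) -> LabeledSample:
    """A 66-curve demonstration fixture for the cluster-size role of k.

    Three 20-curve clusters of distinct shapes (rising, falling,
    cosine), each fanned out by a bounded random amplitude factor
    (uniform in 1 +/- 0.15) plus light GP noise; a tight 5-curve
    micro-cluster offset from the cosine cluster; and one far-away flat
    singleton.  ``labels`` marks only the singleton (cluster id 0); the
    micro-cluster carries id 4 so k-sensitivity demonstrations can tell
    it apart.

    The geometry is arranged so that, with the detector at p = 2..4 and
    the default seed, averaging over k in [1, 5] flags only the
    singleton (each micro-cluster member still has four close
    companions), while k in (5, 10] also flags the whole micro-cluster
    (its members lose their mutual support once k exceeds the group
    size).  The amplitude variation is bounded, not Gaussian, so the big
    clusters contain no accidental lonely stragglers; the contrast
    between the micro-cluster's external gap and the within-cluster
    spread is deliberately moderate — k near the micro-cluster size is
    the boundary the fixture illustrates — so the demonstration is a
    property of this seeded fixture, not of every random draw.
    """
    grid = np.linspace(0.0, 1.0, 25)
    shapes = {
        1: 10.0 * grid,
        2: 10.0 * (1.0 - grid),
        3: 5.0 + 5.0 * np.cos(2.0 * np.pi * grid),
    }
    parts, ids = [], []
    for cid in (1, 2, 3):
        rng = np.random.default_rng(derive_seed(seed, 10 + cid))
        amps = rng.uniform(0.85, 1.15, size=(20, 1))
        parts.append(amps * shapes[cid] + 0.3 * sample_gp_noise(20, grid, rng))
        ids.append(np.full(20, cid))
    rng = np.random.default_rng(derive_seed(seed, 14))
    parts.append(shapes[3] + 4.0 + 0.3 * sample_gp_noise(5, grid, rng))
    ids.append(np.full(5, 4))
    rng = np.random.default_rng(derive_seed(seed, 15))
    parts.append(np.full((1, grid.size), 20.0) + 0.3 * sample_gp_noise(1, grid, rng))
    ids.append(np.zeros(1, dtype=int))
    values = np.vstack(parts)
    cluster_ids = np.concatenate(ids)
    basis = make_discrete_basis(25, 0.0, 1.0)
    sample = FunctionalSample(values, basis, grid=grid)
    return LabeledSample(sample, cluster_ids == 0, cluster_ids)
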