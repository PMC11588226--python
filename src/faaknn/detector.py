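"""Subspace-ensemble functional outlier detection (FAA + kNN).

The detector runs in two stages.  First the curves are projected into a
family of archetype mixture-coefficient spaces: for every archetype count
``p`` between ``p1`` and ``p2`` an archetype analysis is fitted and each
curve is represented by its mixture-weight row ``alpha_i`` (which lives
on the ``p``-simplex, so the scale is comparable across ``p``).  Because
archetypes sit on the convex-hull boundary and do not nest across ``p``,
each projection exposes a different view of the data in which atypical
curves become separable.  Second, each projection is scored with the
k-nearest-neighbor distance score — the sum of Euclidean distances from
a point to its ``k`` nearest neighbors — and the per-(p, k) scores are
averaged into a single ensemble score per curve.  Averaging over the
projection ensemble (and optionally a range of ``k``) reduces the
variance of the identification without changing the score scale.

``k`` controls the cluster size that can be flagged: a group of more
than ``k`` mutually close curves keeps all its members' scores small, so
micro-clusters up to size ``k`` are treated as outlying while larger
clusters are not.

Scores are continuous; ``harden_scores`` turns them into binary labels
with the standard upper boxplot fence Q3 + 1.5·IQR (outlierness is
one-sided: small scores mean typical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._util import check_finite, derive_seed
from .archetypal import fit_archetypes


@dataclass(frozen=True)
class DetectorConfig:
    """Settings of the projection-ensemble detector.

    ``p1``/``p2`` bound the archetype counts (``p1`` is ideally the RSS
    elbow); ``k_values`` is the set of neighbor counts to average over;
    ``n_restarts`` random initializations are used per archetype fit.
    """

    p1: int
    p2: int
    k_values: tuple[int, ...]
    n_restarts: int = 10
    seed: int = 0
    harden: bool = True
    max_iter: int = 150
    tol: float = 1e-6

    def __post_init__(self):
        if not 1 <= self.p1 <= self.p2:
            raise ValueError(f"need 1 <= p1 <= p2, got p1={self.p1}, p2={self.p2}")
        ks = tuple(sorted(set(int(k) for k in self.k_values)))
        if not ks or ks[0] < 1:
            raise ValueError("k_values must be a non-empty set of counts >= 1")
        object.__setattr__(self, "k_values", ks)


@dataclass
class OutlierResult:
    """Ensemble scores, per-(p, k) components and optional hard labels."""

    scores: np.ndarray
    components: dict[tuple[int, int], np.ndarray] = field(repr=False)
    labels: np.ndarray | None = None
    threshold: float | None = None
    rss_by_p: dict[int, float] | None = None

    def top(self, q: int) -> np.ndarray:
        """Indices of the q highest-scoring curves, best first."""
        order = np.argsort(-self.scores, kind="stable")
        return order[:q]


def _knn_scores_from_dist(D: np.ndarray, k: int) -> np.ndarray:
    """Scores from a pairwise distance matrix with +inf on the diagonal."""
    part = np.partition(D, k - 1, axis=1)[:, :k]
    return part.sum(axis=1)


def knn_score(points: np.ndarray, k: int) -> np.ndarray:
    """Sum of Euclidean distances to the k nearest neighbors (self excluded).

    Exact brute-force computation of the full pairwise distance matrix;
    ties are resolved in stable index order, which cannot change the
    score (tied neighbors contribute equal distances).
    """
    points = check_finite(np.atleast_2d(points), "points")
    n = points.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k too large: need 1 <= k <= n-1 = {n - 1}, got {k}")
    D = cdist(points, points)
    np.fill_diagonal(D, np.inf)
    return _knn_scores_from_dist(D, k)


def harden_scores(scores: np.ndarray) -> tuple[np.ndarray, float]:
    """Binary labels from continuous scores via the upper boxplot fence.

    Flags every score above Q3 + 1.5·IQR (quartiles by linear
    interpolation).  Only the upper side flags: low scores indicate
    normality by construction.
    """
    scores = check_finite(scores, "scores").ravel()
    if scores.size < 4:
        raise ValueError("need at least 4 scores to apply the boxplot rule")
    q1, q3 = np.percentile(scores, [25.0, 75.0])
    threshold = float(q3 + 1.5 * (q3 - q1))
    return scores > threshold, threshold


def detect(X, config: DetectorConfig) -> OutlierResult:
    """Run the full projection-ensemble detector on a sample.

    For each ``p`` in ``[p1, p2]`` fits archetypes (best of
    ``n_restarts``; the restart streams are derived from
    ``(seed, p, restart)``, so widening the ``p`` range never perturbs
    existing components), scores the mixture-weight matrix with every
    ``k`` in ``k_values`` and averages all (p, k) components into the
    final score.  With ``config.harden`` the boxplot rule also produces
    binary labels.
    """
    n = X.n if hasattr(X, "n") else np.asarray(X).shape[0]
    k_max = max(config.k_values)
    if n < k_max + 1:
        raise ValueError(f"need at least k+1 = {k_max + 1} curves, got {n}")
    components: dict[tuple[int, int], np.ndarray] = {}
    rss_by_p: dict[int, float] = {}
    for p in range(config.p1, config.p2 + 1):
        model = fit_archetypes(
            X, p,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=derive_seed(config.seed, p),
        )
        rss_by_p[p] = model.rss
        D = cdist(model.alpha, model.alpha)
        np.fill_diagonal(D, np.inf)
        for k in config.k_values:
            components[(p, k)] = _knn_scores_from_dist(D, k)
    scores = np.mean(np.stack(list(components.values())), axis=0)
    labels, threshold = (None, None)
    if config.harden:
        labels, threshold = harden_scores(scores)
    return OutlierResult(scores, components, labels, threshold, rss_by_p)
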