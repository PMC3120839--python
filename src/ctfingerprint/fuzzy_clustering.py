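"""Fuzzy c-means and k-means partitioning of cells, with projection.

Fuzzy c-means (FCM) assigns each cell a partial membership ``u_ij in [0, 1]``
in every cluster (rows sum to 1), controlled by the fuzziness coefficient
``m > 1``: as ``m -> 1`` memberships harden to k-means, as ``m -> inf`` they
flatten to ``1/k``.  The objective minimized by alternating updates is

    J_m = sum_ij u_ij^m d(x_i, c_j)^2

with memberships  ``u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1))``  and centroids
``c_j = sum_i u_ij^m x_i / sum_i u_ij^m``.  Distances are Minkowski of order
p (Euclidean p=2 by default; Manhattan p=1).  For non-Euclidean metrics the
weighted-mean centroid update is retained as the common generalized-FCM
approximation rather than the metric-specific minimizer.

Centroids fit on one population can be held fixed and a second population
projected onto them, yielding per-cluster occupancy fractions — the device
used to compare sorted populations against a reference partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from .ct_data import ExpressionMatrix
from .errors import ValidationError

log = logging.getLogger(__name__)

_D_EPS = 1e-12          # below this a cell is "coincident" with a centroid
_MONOTONE_RTOL = 1e-9   # slack on the objective-monotonicity in-loop check


@dataclass(frozen=True)
class DistanceMetric:
    """Minkowski family metric: euclidean (p=2), manhattan (p=1), minkowski (p)."""

    name: str = "euclidean"
    order: float = 2.0

    def __post_init__(self) -> None:
        canon = {"euclidean": 2.0, "manhattan": 1.0}
        if self.name in canon:
            object.__setattr__(self, "order", canon[self.name])
        elif self.name != "minkowski":
            raise ValidationError(f"unknown metric {self.name!r}")
        if self.order < 1:
            raise ValidationError("Minkowski order must be >= 1")

    @property
    def p(self) -> float:
        return self.order


EUCLIDEAN = DistanceMetric("euclidean")
MANHATTAN = DistanceMetric("manhattan")


def minkowski(order: float) -> DistanceMetric:
    return DistanceMetric("minkowski", order)


def _distances(X: np.ndarray, C: np.ndarray, metric: DistanceMetric) -> np.ndarray:
    return cdist(X, C, metric="minkowski", p=metric.p)


@dataclass
class OccupancyTable:
    """Per-cluster fractions of hard-assigned cells (sum to 1)."""

    fractions: np.ndarray
    population_label: str = ""
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, float)
        if np.any(self.fractions < 0) or abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValidationError("occupancy fractions must be >= 0 and sum to 1")


@dataclass
class ClusterModel:
    """A fitted soft (or hard) partition: centroids + memberships + settings."""

    centroids: np.ndarray
    memberships: np.ndarray
    m: float
    k: int
    metric: DistanceMetric
    objective: float
    n_iter: int
    converged: bool
    seed: int
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def hard_labels(self) -> np.ndarray:
        """Argmax membership per cell; ties resolve to the lowest cluster index."""
        return self.memberships.argmax(axis=1)

    def occupancy(self, population_label: str = "") -> OccupancyTable:
        counts = np.bincount(self.hard_labels, minlength=self.k)
        return OccupancyTable(counts / counts.sum(), population_label, counts)


def _memberships(D: np.ndarray, m: float) -> np.ndarray:
    """FCM membership update from a cells x k distance matrix.

    Computed in the log domain (exponent 2/(m-1) explodes as m -> 1).  Cells
    coincident with a centroid get full membership there.
    """
    n, k = D.shape
    if k == 1:
        return np.ones((n, 1))
    u = np.zeros((n, k))
    coincident = D.min(axis=1) < _D_EPS
    if coincident.any():
        u[coincident, D[coincident].argmin(axis=1)] = 1.0
    rest = ~coincident
    if rest.any():
        logw = (-2.0 / (m - 1.0)) * np.log(D[rest])
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        u[rest] = w / w.sum(axis=1, keepdims=True)
    return u


def _kpp_init(X: np.ndarray, k: int, rng: np.random.Generator,
              metric: DistanceMetric, jitter: bool = False) -> np.ndarray:
    """k-means++-style seeding: D^2-weighted farthest-point sampling.

    With ``jitter`` the seeds are nudged off the data points: a centroid that
    starts exactly on a cell makes that cell's membership one-hot, and at
    large fuzziness the ``u^m`` weights of all other cells vanish, pinning a
    degenerate fixed point at the data point.
    """
    n = X.shape[0]
    centroids = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = _distances(X, np.asarray(centroids), metric).min(axis=1) ** 2
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centroids
            centroids.append(X[rng.integers(n)])
            continue
        centroids.append(X[rng.choice(n, p=d2 / total)])
    C = np.asarray(centroids, dtype=float)
    if jitter:
        scale = 1e-4 * X.std()
        if scale > 0:
            C = C + rng.normal(0.0, scale, C.shape)
    return C


def _fcm_single(X: np.ndarray, k: int, m: float, metric: DistanceMetric,
                rng: np.random.Generator, tol: float, max_iter: int):
    C = _kpp_init(X, k, rng, metric, jitter=True)
    prev_obj = np.inf
    prev_u = None
    converged = False
    for it in range(1, max_iter + 1):
        D = _distances(X, C, metric)
        u = _memberships(D, m)
        obj = float((u ** m * D ** 2).sum())
        if obj > prev_obj * (1 + _MONOTONE_RTOL) + 1e-15:
            # generalized (non-Euclidean) centroid update is approximate; stop
            log.debug("objective rose (%.3e -> %.3e); stopping", prev_obj, obj)
            u, obj = prev_u, prev_obj
            converged = True
            break
        du = np.inf if prev_u is None else np.abs(u - prev_u).max()
        rel = abs(prev_obj - obj) / max(abs(prev_obj), 1.0)
        if du < tol or rel < tol:
            prev_u, prev_obj = u, obj
            converged = True
            break
        prev_u, prev_obj = u, obj
        w = u ** m
        colsum = w.sum(axis=0)
        empty = colsum < _D_EPS
        if empty.any():
            # re-seed starved centroids at the farthest point from the rest
            far = _distances(X, C[~empty], metric).min(axis=1).argmax() if (~empty).any() \
                else rng.integers(X.shape[0])
            for j in np.flatnonzero(empty):
                C[j] = X[far]
            log.info("re-seeded %d starved FCM centroid(s)", int(empty.sum()))
            colsum = np.where(empty, 1.0, colsum)
        C = (w.T @ X) / colsum[:, None]
        # weighted mean keeps centroids defined for coincident one-hot rows
    return C, prev_u, prev_obj, it, converged


def fcm_fit(e: ExpressionMatrix, k: int, m: float,
            metric: DistanceMetric = EUCLIDEAN, n_restarts: int = 20,
            seed: int = 0, tol: float = 1e-6, max_iter: int = 1000) -> ClusterModel:
    """Fit fuzzy c-means from ``n_restarts`` seeded initializations; best kept.

    ``k = 1`` is the degenerate fit (centroid = mean, all memberships 1);
    otherwise ``m`` must exceed 1.  Non-convergence within ``max_iter`` is
    returned with ``converged=False`` and a warning.
    """
    X = e.values
    if k < 1 or k > X.shape[0]:
        raise ValidationError(f"k={k} must lie in [1, n_cells={X.shape[0]}]")
    if k > 1 and m <= 1.0:
        raise ValidationError("fuzziness coefficient m must be > 1")
    best = None
    rngs = np.random.default_rng(seed).spawn(max(1, n_restarts))
    for rng in rngs:
        C, u, obj, n_it, conv = _fcm_single(X, k, m, metric, rng, tol, max_iter)
        if best is None or obj < best[2]:
            best = (C, u, obj, n_it, conv)
    C, u, obj, n_it, conv = best
    if not conv:
        warnings.warn(f"FCM did not converge within {max_iter} iterations "
                      f"(k={k}, m={m})", stacklevel=2)
    return ClusterModel(C, u, m, k, metric, obj, n_it, conv, seed,
                        list(e.cell_ids), list(e.gene_ids))


# ---------------------------------------------------------------------------
# Hard k-means (Lloyd)


def _kmeans_single(X: np.ndarray, k: int, rng: np.random.Generator,
                   max_iter: int):
    C = _kpp_init(X, k, rng, EUCLIDEAN)
    labels = None
    for it in range(1, max_iter + 1):
        D = _distances(X, C, EUCLIDEAN)
        new_labels = D.argmin(axis=1)
        for j in range(k):
            members = new_labels == j
            if not members.any():
                far = D.min(axis=1).argmax()
                C[j] = X[far]
                new_labels[far] = j
                log.info("k-means: re-seeded empty cluster %d at farthest point", j)
            else:
                C[j] = X[members].mean(axis=0)
        if labels is not None and np.array_equal(labels, new_labels):
            labels = new_labels
            return C, labels, it, True
        labels = new_labels
    return C, labels, max_iter, False


def kmeans_fit(e: ExpressionMatrix, k: int, n_restarts: int = 20,
               seed: int = 0, max_iter: int = 300) -> ClusterModel:
    """Hard k-means (Lloyd, Euclidean); memberships are one-hot."""
    X = e.values
    if k < 1 or k > X.shape[0]:
        raise ValidationError(f"k={k} must lie in [1, n_cells={X.shape[0]}]")
    best = None
    for rng in np.random.default_rng(seed).spawn(max(1, n_restarts)):
        C, labels, n_it, conv = _kmeans_single(X, k, rng, max_iter)
        obj = float(((X - C[labels]) ** 2).sum())
        if best is None or obj < best[0]:
            best = (obj, C, labels, n_it, conv)
    obj, C, labels, n_it, conv = best
    u = np.zeros((X.shape[0], k))
    u[np.arange(X.shape[0]), labels] = 1.0
    return ClusterModel(C, u, 1.0, k, EUCLIDEAN, obj, n_it, conv, seed,
                        list(e.cell_ids), list(e.gene_ids))


# ---------------------------------------------------------------------------
# Projection and partition comparison


def project_population(model: ClusterModel,
                       e_new: ExpressionMatrix) -> tuple[np.ndarray, OccupancyTable]:
    """Membership of new cells under FIXED centroids (no refit).

    Uses the fitted model's fuzziness and metric; occupancy is the fraction of
    cells hard-assigned to each cluster by argmax membership (ties to the
    lowest cluster index).
    """
    if list(e_new.gene_ids) != list(model.gene_ids):
        if set(e_new.gene_ids) == set(model.gene_ids):
            e_new = e_new.subset_genes(list(model.gene_ids))
        else:
            raise ValidationError("gene panel mismatch between model and new population")
    D = _distances(e_new.values, model.centroids, model.metric)
    if model.m > 1.0:
        u = _memberships(D, model.m)
    else:  # hard model: nearest-centroid one-hot
        u = np.zeros((e_new.n_cells, model.k))
        u[np.arange(e_new.n_cells), D.argmin(axis=1)] = 1.0
    labels = u.argmax(axis=1)
    counts = np.bincount(labels, minlength=model.k)
    return u, OccupancyTable(counts / counts.sum(), e_new.population_label, counts)


def partition_agreement(a: ClusterModel, b: ClusterModel) -> float:
    """Adjusted Rand index of the two hard partitions (same cells required)."""
    if list(a.cell_ids) != list(b.cell_ids):
        raise ValidationError("partitions were fit on different cells")
    return float(adjusted_rand_score(a.hard_labels, b.hard_labels))
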