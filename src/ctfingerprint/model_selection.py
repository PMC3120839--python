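"""AICc model selection over a (cluster number, fuzziness) grid.

A fitted fuzzy partition is scored by a spherical-Gaussian mixture
pseudo-likelihood that treats the FCM memberships as responsibilities:

    pi_j     = mean membership of cluster j
    sigma^2  = sum_ij u_ij d_ij^2 / (n * g)       (pooled, Euclidean d)
    log L    = sum_i log sum_j pi_j N(x_i; c_j, sigma^2 I)
    K        = k*g + (k - 1) + 1                  (centroids + weights + variance)
    AIC      = -2 log L + 2 K
    AICc     = AIC + 2 K (K + 1) / (n - K - 1)

This reduces to the exact spherical-Gaussian AIC at k = 1 and varies smoothly
with the fuzziness coefficient through the memberships.  The fuzziness is
treated as a selected hyperparameter, not a counted parameter (counting it
would add a constant 2 across the m-grid and cannot move the argmin in m).
The AICc small-sample size n is the number of cells.

Grid scores are summarized by AIC differences Delta_i = AICc_i - min AICc,
Akaike weights w_i = exp(-Delta_i/2) / sum_l exp(-Delta_l/2) (the weight of
evidence for model i being the best of those evaluated), and evidence ratios
w_best / w_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.spatial.distance import cdist

from .ct_data import ExpressionMatrix
from .errors import AICcUndefinedError, OptimizationError, ValidationError
from .fuzzy_clustering import (ClusterModel, DistanceMetric, EUCLIDEAN, fcm_fit)

log = logging.getLogger(__name__)


def _default_m_values() -> tuple[float, ...]:
    return tuple(round(1.05 + 0.05 * i, 2) for i in range(40))  # 1.05 .. 3.00


@dataclass(frozen=True)
class ModelGrid:
    """Exhaustive (k, m) grid; defaults k = 1..6, m = 1.05..3.00 step 0.05."""

    k_values: tuple = tuple(range(1, 7))
    m_values: tuple = field(default_factory=_default_m_values)

    def __post_init__(self) -> None:
        if not self.k_values or not self.m_values:
            raise ValidationError("grid must contain at least one k and one m")
        if min(self.k_values) < 1:
            raise ValidationError("cluster counts must be >= 1")
        if min(self.m_values) <= 1.0:
            raise ValidationError("all fuzziness values must exceed 1")

    def points(self):
        for k in self.k_values:
            for m in self.m_values:
                yield k, m


@dataclass
class ModelScore:
    k: int
    m: float
    log_likelihood: float
    n_params: int
    aic: float
    aicc: float
    delta_aic: float | None = None
    akaike_weight: float | None = None
    evidence_ratio: float | None = None


def score_model(model: ClusterModel, e: ExpressionMatrix) -> ModelScore:
    """AICc score of a fitted partition on the matrix it was fit to.

    Raises :class:`AICcUndefinedError` when ``n <= K + 1`` (the second-order
    correction's denominator vanishes or turns negative).
    """
    X = e.values
    n, g = X.shape
    k = model.k
    D2 = cdist(X, model.centroids, metric="sqeuclidean")
    u = model.memberships
    sigma2 = max(float((u * D2).sum()) / (n * g), 1e-12)
    pi = u.mean(axis=0)
    with np.errstate(divide="ignore"):
        log_pi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), -np.inf)
    log_phi = -0.5 * (g * np.log(2 * np.pi * sigma2) + D2 / sigma2)
    logl = float(logsumexp(log_pi[None, :] + log_phi, axis=1).sum())
    n_params = k * g + (k - 1) + 1
    aic = -2.0 * logl + 2.0 * n_params
    if n - n_params - 1 <= 0:
        raise AICcUndefinedError(
            f"AICc undefined: n={n} <= K+1={n_params + 1} (k={k}, g={g})")
    aicc = aic + 2.0 * n_params * (n_params + 1) / (n - n_params - 1)
    return ModelScore(k, model.m, logl, n_params, aic, aicc)


def annotate_scores(scores: list[ModelScore]) -> int:
    """Fill Delta, Akaike weights and evidence ratios in place; return best index.

    Best = lowest AICc, ties broken by smaller k then smaller m.
    """
    if not scores:
        raise OptimizationError("no scores to annotate")
    order = sorted(range(len(scores)),
                   key=lambda i: (scores[i].aicc, scores[i].k, scores[i].m))
    best = order[0]
    aicc = np.array([s.aicc for s in scores])
    delta = aicc - aicc[best]
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    with np.errstate(over="ignore"):  # huge Delta -> evidence ratio inf, fine
        ratios = np.exp(delta / 2.0)  # w_best / w_i
    for i, s in enumerate(scores):
        s.delta_aic = float(delta[i])
        s.akaike_weight = float(w[i])
        s.evidence_ratio = float(ratios[i])
    return best


def optimize_grid(e: ExpressionMatrix, grid: ModelGrid | None = None,
                  seed: int = 0, metric: DistanceMetric = EUCLIDEAN,
                  n_restarts: int = 5, tol: float = 1e-6,
                  max_iter: int = 1000) -> tuple[ClusterModel, list[ModelScore]]:
    """Fit and score every (k, m) grid point; return the AICc-best model.

    Every point gets its own deterministic restart seed derived from ``seed``.
    Points where AICc is undefined (n too small for K) are skipped with a
    warning; if all points are skipped an :class:`OptimizationError` is raised.
    """
    if grid is None:
        grid = ModelGrid()
    pts = list(grid.points())
    child_seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=len(pts))
    scores: list[ModelScore] = []
    models: list[ClusterModel] = []
    for (k, m), s in zip(pts, child_seeds):
        model = fcm_fit(e, k, m, metric=metric, n_restarts=n_restarts,
                        seed=int(s), tol=tol, max_iter=max_iter)
        try:
            scores.append(score_model(model, e))
            models.append(model)
        except AICcUndefinedError as err:
            log.warning("skipping grid point (k=%d, m=%.2f): %s", k, m, err)
    if not scores:
        raise OptimizationError("every grid point was skipped; AICc undefined throughout")
    best = annotate_scores(scores)
    return models[best], scores


def model_selection_report(scores: list[ModelScore]) -> pd.DataFrame:
    """Scores as a table sorted by AIC difference (best model first)."""
    if not scores:
        raise ValidationError("no scores to report")
    if scores[0].delta_aic is None:
        annotate_scores(scores)
    df = pd.DataFrame([{
        "k": s.k, "m": s.m, "log_likelihood": s.log_likelihood,
        "n_params": s.n_params, "aicc": s.aicc, "delta_aic": s.delta_aic,
        "akaike_weight": s.akaike_weight, "evidence_ratio": s.evidence_ratio,
    } for s in scores])
    return df.sort_values(["delta_aic", "k", "m"], kind="stable").reset_index(drop=True)
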