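"""Cluster-stability diagnostics.

Three procedures probe whether a selected partition is an artifact of the
particular cells, genes or algorithm used:

* ``bootstrap_cluster_number`` — re-run the AICc grid search on random 70%
  subsets of cells (without replacement by default) and tabulate how often
  each cluster number wins.
* ``prediction_strength`` — Tibshirani-Walther cross-validated cluster
  validity for k-means: test cells are clustered on their own and classified
  by nearest training centroid; a k is credible when, for every test cluster,
  most within-cluster pairs are also co-assigned by the training model.  The
  chosen k is the largest one whose mean prediction strength exceeds the
  threshold (0.8 by convention); ps(1) = 1 by definition.
* ``gene_panel_sensitivity`` — repeat the grid search on alternative gene
  panels and compare partitions to a reference panel by adjusted Rand index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from .ct_data import ExpressionMatrix
from .errors import ValidationError
from .fuzzy_clustering import kmeans_fit
from .model_selection import ModelGrid, optimize_grid

log = logging.getLogger(__name__)


@dataclass
class BootstrapClusterReport:
    n_iterations: int
    subsample_fraction: float
    k_frequencies: dict[int, float]
    mean_k: float
    sd_k: float
    selected_k: list[int] = field(default_factory=list)

    @property
    def modal_k(self) -> int:
        return max(self.k_frequencies, key=lambda k: (self.k_frequencies[k], -k))


def bootstrap_cluster_number(e: ExpressionMatrix, grid: ModelGrid | None = None,
                             fraction: float = 0.7, n_iterations: int = 100,
                             seed: int = 0, n_restarts: int = 3,
                             replace: bool = False) -> BootstrapClusterReport:
    """Distribution of the AICc-optimal cluster number over cell subsamples.

    Each iteration draws ``round(fraction * n)`` cells (without replacement by
    default; ``replace=True`` for a classical bootstrap), re-runs
    :func:`optimize_grid`, and records the winning k.
    """
    if grid is None:
        grid = ModelGrid()
    if not (0 < fraction <= 1):
        raise ValidationError("subsample fraction must lie in (0, 1]")
    n = e.n_cells
    size = int(round(fraction * n))
    if size < max(grid.k_values):
        raise ValidationError(
            f"subsample of {size} cells cannot support k up to {max(grid.k_values)}")
    if fraction == 1.0 and not replace:
        log.info("fraction=1.0 without replacement: only restart seeds vary")
    rng = np.random.default_rng(seed)
    iter_seeds = rng.integers(0, 2 ** 31 - 1, size=n_iterations)
    ks = []
    for s in iter_seeds:
        sub_rng = np.random.default_rng(int(s))
        idx = sub_rng.choice(n, size=size, replace=replace)
        best, _ = optimize_grid(e.subset_cells(np.sort(idx)), grid,
                                seed=int(s), n_restarts=n_restarts)
        ks.append(best.k)
    ks_arr = np.array(ks)
    freqs = {int(k): float((ks_arr == k).mean()) for k in np.unique(ks_arr)}
    return BootstrapClusterReport(n_iterations, fraction, freqs,
                                  float(ks_arr.mean()), float(ks_arr.std()), ks)


@dataclass
class PredictionStrengthReport:
    k_values: tuple
    mean_ps: dict[int, float]
    sd_ps: dict[int, float]
    chosen_k: int
    threshold: float = 0.8
    n_folds: int = 5
    n_iterations: int = 100


def _fold_ps(X_train: np.ndarray, X_test: np.ndarray, k: int,
             seed: int, n_restarts: int) -> float:
    """Prediction strength of one train/test split for one k."""
    if k == 1:
        return 1.0
    e_tr = _as_matrix(X_train)
    e_te = _as_matrix(X_test)
    train = kmeans_fit(e_tr, k, n_restarts=n_restarts, seed=seed)
    test = kmeans_fit(e_te, k, n_restarts=n_restarts, seed=seed + 1)
    # classify test cells by nearest TRAIN centroid
    train_side = cdist(X_test, train.centroids).argmin(axis=1)
    ps_per_cluster = []
    for c in range(k):
        members = np.flatnonzero(test.hard_labels == c)
        n_c = members.size
        if n_c < 2:
            ps_per_cluster.append(1.0)  # too small to falsify co-membership
            continue
        counts = np.bincount(train_side[members])
        co_pairs = float((counts * (counts - 1)).sum()) / 2.0
        all_pairs = n_c * (n_c - 1) / 2.0
        ps_per_cluster.append(co_pairs / all_pairs)
    return min(ps_per_cluster)


def _as_matrix(X: np.ndarray) -> ExpressionMatrix:
    bound = max(5.0, float(np.abs(X).max()) + 1.0)
    return ExpressionMatrix(X, [f"c{i}" for i in range(X.shape[0])],
                            [f"g{j}" for j in range(X.shape[1])],
                            clamp_bound=bound)


def prediction_strength(e: ExpressionMatrix, k_values=(1, 2, 3, 4, 5, 6),
                        n_folds: int = 5, n_iterations: int = 100,
                        threshold: float = 0.8, seed: int = 0,
                        n_restarts: int = 3) -> PredictionStrengthReport:
    """Cross-validated prediction strength per k; choose the largest passing k."""
    if n_folds < 2:
        raise ValidationError("need at least 2 folds")
    if min(k_values) < 1:
        raise ValidationError("k values must be >= 1")
    X = e.values
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    per_k: dict[int, list[float]] = {k: [] for k in k_values}
    for it in range(n_iterations):
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, test_idx)
            fold_seed = int(rng.integers(0, 2 ** 31 - 2))
            for k in k_values:
                per_k[k].append(_fold_ps(X[train_idx], X[test_idx], k,
                                         fold_seed, n_restarts))
    mean_ps = {k: float(np.mean(v)) for k, v in per_k.items()}
    sd_ps = {k: float(np.std(v)) for k, v in per_k.items()}
    passing = [k for k in k_values if mean_ps[k] > threshold]
    chosen = max(passing) if passing else min(k_values)
    return PredictionStrengthReport(tuple(k_values), mean_ps, sd_ps, chosen,
                                    threshold, n_folds, n_iterations)


def gene_panel_sensitivity(e: ExpressionMatrix, panels: list[list[str]],
                           grid: ModelGrid | None = None, seed: int = 0,
                           n_restarts: int = 3) -> pd.DataFrame:
    """Grid-search each gene panel; compare partitions to the first (reference).

    Returns a table with one row per panel: panel index, its genes, the
    AICc-best (k, m) and the adjusted Rand index against the reference
    partition (1.0 for the reference itself).
    """
    if not panels:
        raise ValidationError("no gene panels given")
    for p in panels:
        if not p:
            raise ValidationError("empty gene panel")
    if grid is None:
        grid = ModelGrid()
    rows = []
    ref_labels = None
    for i, panel in enumerate(panels):
        best, _ = optimize_grid(e.subset_genes(list(panel)), grid,
                                seed=seed, n_restarts=n_restarts)
        labels = best.hard_labels
        if ref_labels is None:
            ref_labels = labels
        rows.append({
            "panel": i, "genes": ",".join(panel), "n_genes": len(panel),
            "best_k": best.k, "best_m": best.m,
            "ari_vs_reference": float(adjusted_rand_score(ref_labels, labels)),
        })
    return pd.DataFrame(rows)
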