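"""Coefficient-of-variance statistics with bootstrap uncertainty.

The univariate coefficient of variance (COV) of one gene's per-cell values is
``sd / mean`` (sample sd, n-1 denominator).  The multivariate generalization
over a gene set (Van Valen's form) pools variances and squared means:

    cv_n = sqrt(sum_i sigma_i^2) / sqrt(sum_i mu_i^2)

which is dimensionless and invariant to rescaling all values by a common
positive factor.  Bootstrap standard errors resample cells with replacement.

COV is a ratio statistic and only meaningful on a positive scale; Ct values
qualify directly, whereas median-centred log2 expression (mean ~ 0) does not.
``cov_table`` therefore works on the Ct scale by default, with an optional
linear scale ``2^(lod - Ct)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_data import CtMatrix
from .errors import UndefinedCovError, ValidationError

log = logging.getLogger(__name__)

DEFAULT_N_BOOT = 100_000


@dataclass
class CovEstimate:
    gene_id: str
    cov: float
    boot_sd: float | None = None
    n_boot: int = 0


def _cov(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0.0:
        raise UndefinedCovError("COV undefined: mean is zero")
    return float(values.std(ddof=1) / mean)


def gene_cov(values, gene_id: str = "gene") -> CovEstimate:
    """Univariate COV = sample sd / mean of one gene's per-cell values."""
    values = np.asarray(values, float)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError("gene_cov needs a 1-D vector of >= 2 values")
    return CovEstimate(gene_id, _cov(values))


def multivariate_cov(matrix, genes=None) -> CovEstimate:
    """Van Valen multivariate COV over a gene subset.

    ``matrix`` is any cells x genes container with ``values`` and ``gene_ids``
    (CtMatrix works directly); ``genes`` defaults to the full panel.
    """
    if genes is None:
        genes = list(matrix.gene_ids)
    sub = matrix.subset_genes(list(genes))
    vals = sub.values
    if vals.shape[0] < 2:
        raise ValidationError("multivariate COV needs >= 2 cells")
    var = vals.var(axis=0, ddof=1)
    mu = vals.mean(axis=0)
    denom = np.sqrt(np.sum(mu ** 2))
    if denom == 0.0:
        raise UndefinedCovError("multivariate COV undefined: all gene means are zero")
    return CovEstimate("multivariate", float(np.sqrt(var.sum()) / denom))


def bootstrap_cov_sd(values, n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
                     gene_id: str = "gene") -> CovEstimate:
    """Bootstrap standard deviation of the univariate COV.

    Cells are resampled with replacement ``n_boot`` times; resamples whose
    mean is exactly zero (COV undefined) are redrawn and logged.
    """
    values = np.asarray(values, float)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError("bootstrap_cov_sd needs a 1-D vector of >= 2 values")
    n = values.size
    rng = np.random.default_rng(seed)
    covs = np.empty(n_boot)
    filled = 0
    redrawn = 0
    while filled < n_boot:
        chunk = min(n_boot - filled, 200_000)
        idx = rng.integers(0, n, size=(chunk, n))
        draws = values[idx]
        means = draws.mean(axis=1)
        ok = means != 0.0
        redrawn += int((~ok).sum())
        draws, means = draws[ok], means[ok]
        sds = draws.std(axis=1, ddof=1)
        take = min(draws.shape[0], n_boot - filled)
        covs[filled:filled + take] = (sds / means)[:take]
        filled += take
    if redrawn:
        log.info("bootstrap_cov_sd: redrew %d zero-mean resamples", redrawn)
    return CovEstimate(gene_id, _cov(values), float(covs.std(ddof=1)), n_boot)


def cov_table(ct: CtMatrix, n_boot: int = 0, seed: int = 0,
              scale: str = "ct") -> pd.DataFrame:
    """Per-gene COV table (columns: gene, cov, boot_sd, n).

    ``scale='ct'`` computes COV of raw Ct values; ``scale='linear'`` of the
    linear-expression proxy ``2^(lod_ct - Ct)``.
    """
    if scale == "ct":
        vals = ct.values
    elif scale == "linear":
        vals = 2.0 ** (ct.lod_ct - ct.values)
    else:
        raise ValidationError(f"unknown COV scale {scale!r}")
    rows = []
    for j, gene in enumerate(ct.gene_ids):
        col = vals[:, j]
        if n_boot > 0:
            est = bootstrap_cov_sd(col, n_boot, seed=seed + j, gene_id=gene)
        else:
            est = gene_cov(col, gene_id=gene)
        rows.append({"gene": gene, "cov": est.cov,
                     "boot_sd": est.boot_sd, "n": ct.n_cells})
    return pd.DataFrame(rows)
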