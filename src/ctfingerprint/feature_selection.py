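"""Differential-distribution gene selection between two cell populations.

Genes are compared by the two-sample Kolmogorov-Smirnov statistic on per-cell
expression, with Bonferroni control of the family-wise error over the panel.
An alternate unsupervised route ranks genes by univariate COV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ct_data import CtMatrix, ExpressionMatrix
from .errors import ValidationError
from .variability import gene_cov

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


@dataclass
class GeneTestResult:
    gene_id: str | None
    ks_statistic: float
    p_value: float
    p_adjusted: float | None = None
    selected: bool | None = None


def ks_compare(a, b, gene_id: str | None = None) -> GeneTestResult:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|, asymptotic two-sided p.

    The asymptotic (not exact) p-value is used throughout because Ct data
    carry heavy ties at the detection floor, which invalidate the exact
    no-ties distribution.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("ks_compare needs >= 2 values per sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return GeneTestResult(gene_id, float(res.statistic), float(res.pvalue))


def _tie_fraction(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    return 1.0 - np.unique(pooled).size / pooled.size


def select_differential_genes(pop_a: ExpressionMatrix | CtMatrix,
                              pop_b: ExpressionMatrix | CtMatrix,
                              alpha: float = DEFAULT_ALPHA,
                              n_tests: int | None = None) -> list[GeneTestResult]:
    """Per-gene KS tests with Bonferroni correction over the shared panel.

    ``p_adjusted = min(1, p * n_tests)`` with ``n_tests`` defaulting to the
    number of shared genes; a gene is selected iff ``p_adjusted < alpha``.
    Results are returned in ``pop_a``'s gene order.
    """
    common = [g for g in pop_a.gene_ids if g in set(pop_b.gene_ids)]
    if not common:
        raise ValidationError("populations share no gene ids")
    if n_tests is None:
        n_tests = len(common)
    sub_a = pop_a.subset_genes(common)
    sub_b = pop_b.subset_genes(common)
    results = []
    high_ties = 0
    for j, gene in enumerate(common):
        a, b = sub_a.values[:, j], sub_b.values[:, j]
        if _tie_fraction(a, b) > 0.05:
            high_ties += 1
        r = ks_compare(a, b, gene_id=gene)
        r.p_adjusted = min(1.0, r.p_value * n_tests)
        r.selected = bool(r.p_adjusted < alpha)
        results.append(r)
    if high_ties:
        log.info("select_differential_genes: %d/%d genes have >5%% ties; "
                 "asymptotic KS p-values in use", high_ties, len(common))
    return results


def select_top_cov_genes(matrix: ExpressionMatrix | CtMatrix, n_genes: int) -> list[str]:
    """The ``n_genes`` genes with highest univariate COV, ties broken by id.

    For a CtMatrix the COV is computed on raw Ct values.  For a median-centred
    ExpressionMatrix the per-gene mean is ~0 and a ratio statistic is
    meaningless, so COV is computed on the positive linear scale ``2^e``.
    """
    if n_genes > len(matrix.gene_ids):
        raise ValidationError(
            f"requested {n_genes} genes from a {len(matrix.gene_ids)}-gene panel")
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    vals = matrix.values
    if isinstance(matrix, ExpressionMatrix):
        vals = 2.0 ** vals
    covs = {g: gene_cov(vals[:, j], g).cov for j, g in enumerate(matrix.gene_ids)}
    ranked = sorted(matrix.gene_ids, key=lambda g: (-covs[g], g))
    return ranked[:n_genes]
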