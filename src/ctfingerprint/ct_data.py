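"""Data model, I/O and normalization for single-cell qPCR Ct matrices.

A qPCR cycle threshold (Ct) is the cycle at which a reaction's fluorescence
crosses the detection threshold; each cycle corresponds to roughly a two-fold
amplification, so a HIGHER Ct means LESS starting mRNA.  Reactions that never
amplify within the instrument's cycle limit are "nondetects" and are encoded
at the limit-of-detection floor (40 cycles by convention).

Sign convention for normalized expression
-----------------------------------------
``normalize`` returns ``e = median_gene(Ct) - Ct`` (clamped), so that HIGHER
normalized values mean MORE mRNA.  One unit is one qPCR cycle, i.e. a two-fold
change; the default clamp of +/-5 cycles corresponds to a 32-fold bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

DEFAULT_LOD_CT = 40.0
DEFAULT_CLAMP = 5.0


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what} id(s): {dupes[:5]}")
    return ids


@dataclass
class CtMatrix:
    """Raw cells x genes cycle-threshold values with a nondetect floor.

    Invariants: all values lie in ``(0, lod_ct]``; nondetects are stored
    exactly as ``lod_ct``; cell and gene ids are unique and match the matrix
    dimensions.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    population_label: str = ""
    lod_ct: float = DEFAULT_LOD_CT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D cells x genes matrix")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        n, g = self.values.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("Ct values must be finite")
        if np.any(self.values <= 0) or np.any(self.values > self.lod_ct):
            raise ValidationError(f"Ct values must lie in (0, {self.lod_ct}]")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def nondetect_mask(self) -> np.ndarray:
        return self.values == self.lod_ct

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def subset_genes(self, genes: list[str]) -> "CtMatrix":
        idx = _gene_indices(self.gene_ids, genes)
        return CtMatrix(self.values[:, idx], list(self.cell_ids), list(genes),
                        self.population_label, self.lod_ct)

    def subset_cells(self, indices) -> "CtMatrix":
        indices = np.asarray(indices)
        return CtMatrix(self.values[indices], [self.cell_ids[i] for i in indices],
                        list(self.gene_ids), self.population_label, self.lod_ct)


@dataclass
class ExpressionMatrix:
    """Gene-wise median-centred log2 expression, clamped to ``+/-clamp_bound``.

    Values are ``median_gene(Ct) - Ct`` in cycles (log2 fold change from the
    pooled median); higher means more mRNA.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    population_label: str = ""
    clamp_bound: float = DEFAULT_CLAMP

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D cells x genes matrix")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        n, g = self.values.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(self.gene_ids) == 0:
            raise ValidationError("expression matrix needs at least one gene")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(np.abs(self.values) > self.clamp_bound + 1e-12):
            raise ValidationError(f"values exceed clamp bound +/-{self.clamp_bound}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = _gene_indices(self.gene_ids, genes)
        return ExpressionMatrix(self.values[:, idx], list(self.cell_ids), list(genes),
                                self.population_label, self.clamp_bound)

    def subset_cells(self, indices) -> "ExpressionMatrix":
        indices = np.asarray(indices)
        return ExpressionMatrix(self.values[indices], [self.cell_ids[i] for i in indices],
                                list(self.gene_ids), self.population_label, self.clamp_bound)


def _gene_indices(gene_ids: list[str], genes) -> list[int]:
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValidationError(f"unknown gene id(s): {missing[:5]}")
    if len(genes) == 0:
        raise ValidationError("empty gene subset")
    return [pos[g] for g in genes]


@dataclass(frozen=True)
class ChipLayout:
    """Geometry of a dynamic-array qPCR chip (assays x sample inlets)."""

    n_assays: int = 48
    n_samples: int = 48

    def __post_init__(self) -> None:
        if self.n_assays < 1 or self.n_samples < 1:
            raise ValidationError("chip layout dimensions must be >= 1")


def chip_reaction_count(layout: ChipLayout) -> int:
    """Number of qPCR reactions per chip run: every assay crossed with every sample."""
    return layout.n_assays * layout.n_samples


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _header_ids(path: Path, sep: str) -> list[str]:
    # pandas silently renames duplicate header fields; validate the raw header
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n")
    return header.split(sep)[1:]


def _numeric_frame(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        try:
            # float(str) is correctly rounded, so written tables re-read exactly
            out[col] = df[col].astype(float)
        except (ValueError, TypeError):
            for row, v in df[col].items():
                try:
                    float(v)
                except (ValueError, TypeError):
                    raise ParseError(
                        f"{path}: non-numeric value {v!r} "
                        f"at row {row!r}, column {col!r}") from None
            raise
    return pd.DataFrame(out, index=df.index)


def read_ct_table(path, lod_ct: float = DEFAULT_LOD_CT,
                  population_label: str | None = None) -> CtMatrix:
    """Read a delimited cells x genes Ct table (first column = cell ids).

    Values above ``lod_ct`` and missing entries are floored to ``lod_ct``
    (nondetects); the floored count is logged.  Delimiter is inferred from the
    extension (.csv => comma, otherwise tab).
    """
    path = Path(path)
    _check_unique(_header_ids(path, _sep_for(path)), "gene")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=object)
    cells = _check_unique(df.index, "cell")
    genes = _check_unique(df.columns, "gene")
    num = _numeric_frame(df, path)
    vals = num.to_numpy(dtype=float)
    floored = int(np.sum(~np.isfinite(vals)) + np.sum(vals > lod_ct))
    vals = np.where(np.isfinite(vals), vals, lod_ct)
    vals = np.minimum(vals, lod_ct)
    if floored:
        log.info("read_ct_table(%s): floored %d entr%s to Ct=%g",
                 path.name, floored, "y" if floored == 1 else "ies", lod_ct)
    label = population_label if population_label is not None else path.stem
    return CtMatrix(vals, cells, genes, label, lod_ct)


def read_chip_export(path, lod_ct: float = DEFAULT_LOD_CT,
                     population_label: str | None = None) -> CtMatrix:
    """Reader shim for the wide instrument export of a dynamic-array chip.

    The instrument writes an assay x sample grid (genes as rows, cells as
    columns); this transposes to the package's cells x genes orientation and
    applies the same nondetect flooring as :func:`read_ct_table`.
    """
    path = Path(path)
    _check_unique(_header_ids(path, _sep_for(path)), "cell")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=object)
    genes = _check_unique(df.index, "gene")
    cells = _check_unique(df.columns, "cell")
    vals = _numeric_frame(df, path).to_numpy(dtype=float).T
    vals = np.where(np.isfinite(vals), vals, lod_ct)
    vals = np.minimum(vals, lod_ct)
    label = population_label if population_label is not None else path.stem
    return CtMatrix(vals, cells, genes, label, lod_ct)


def write_ct_table(ct: CtMatrix, path) -> None:
    path = Path(path)
    ct.to_frame().to_csv(path, sep=_sep_for(path))


def write_expression_table(e: ExpressionMatrix, path) -> None:
    """Write a delimited expression table that round-trips losslessly.

    Floats are written with ``repr`` (shortest round-trip) formatting by
    pandas, so ``read_expression_table(write(...))`` reproduces the matrix
    bit-for-bit.
    """
    path = Path(path)
    e.to_frame().to_csv(path, sep=_sep_for(path))


def read_expression_table(path, clamp_bound: float = DEFAULT_CLAMP,
                          population_label: str | None = None) -> ExpressionMatrix:
    path = Path(path)
    _check_unique(_header_ids(path, _sep_for(path)), "gene")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=object)
    cells = _check_unique(df.index, "cell")
    genes = _check_unique(df.columns, "gene")
    vals = _numeric_frame(df, path).to_numpy(dtype=float)
    label = population_label if population_label is not None else path.stem
    return ExpressionMatrix(vals, cells, genes, label, clamp_bound)


# ---------------------------------------------------------------------------
# Normalization


def gene_medians(ct: CtMatrix) -> np.ndarray:
    """Per-gene median Ct over all cells (even n: mean of central pair)."""
    return np.median(ct.values, axis=0)


def normalize(ct: CtMatrix, clamp_bound: float = DEFAULT_CLAMP,
              reference_medians: np.ndarray | None = None) -> ExpressionMatrix:
    """Median-centre each gene and convert to clamped log2 fold change.

    ``e[i, g] = clamp(median_g - Ct[i, g], -clamp_bound, +clamp_bound)`` where
    ``median_g`` is the pooled per-gene median of ``ct`` (or the caller's
    ``reference_medians``, e.g. medians of a larger pooled sample).  Nondetects
    (Ct = lod_ct) fall on the low-expression side and hit the ``-clamp_bound``
    floor whenever the gene's median is at least ``lod_ct - clamp_bound``.
    """
    if ct.n_cells == 0 or ct.n_genes == 0:
        raise ValidationError("cannot normalize an empty matrix")
    med = gene_medians(ct) if reference_medians is None else np.asarray(reference_medians, float)
    if med.shape != (ct.n_genes,):
        raise ValidationError("reference_medians length must equal gene count")
    e = np.clip(med[None, :] - ct.values, -clamp_bound, clamp_bound)
    return ExpressionMatrix(e, list(ct.cell_ids), list(ct.gene_ids),
                            ct.population_label, clamp_bound)


def normalize_populations(mats: list[CtMatrix], clamp_bound: float = DEFAULT_CLAMP,
                          pooled: bool = True) -> list[ExpressionMatrix]:
    """Normalize several populations on a shared gene panel.

    With ``pooled=True`` (default) the per-gene median is taken over all cells
    of all populations pooled together, so the populations stay on one common
    scale — required when projecting one population onto centroids fit on
    another.  With ``pooled=False`` each population is centred on its own
    medians.
    """
    if not mats:
        raise ValidationError("no populations given")
    genes = mats[0].gene_ids
    for m in mats[1:]:
        if m.gene_ids != genes:
            raise ValidationError("populations must share an identical gene panel")
    if not pooled:
        return [normalize(m, clamp_bound) for m in mats]
    pooled_vals = np.vstack([m.values for m in mats])
    med = np.median(pooled_vals, axis=0)
    return [normalize(m, clamp_bound, reference_medians=med) for m in mats]


def filter_genes_by_nondetect(ct: CtMatrix, max_fraction: float) -> CtMatrix:
    """Drop genes whose nondetect fraction exceeds ``max_fraction`` (optional QC)."""
    frac = ct.nondetect_mask.mean(axis=0)
    keep = [g for g, f in zip(ct.gene_ids, frac) if f <= max_fraction]
    if not keep:
        raise ValidationError("no genes survive the nondetect filter")
    dropped = ct.n_genes - len(keep)
    if dropped:
        log.info("nondetect filter dropped %d of %d genes", dropped, ct.n_genes)
    return ct.subset_genes(keep)
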