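"""End-to-end orchestration: normalize -> select genes -> optimize -> project.

``run_pipeline`` executes the full analysis on several cell populations:

1. read each population's Ct table and pool-normalize on shared gene medians;
2. KS-select differential genes (reference vs comparison population);
3. AICc grid-search fuzzy c-means on the reference, restricted to the
   selected genes;
4. project every other population onto the fixed reference centroids and
   tabulate cluster occupancies;
5. optional stability diagnostics (bootstrap of k, prediction strength);
6. order cells hierarchically within clusters and export a heatmap-ready
   matrix; write a manifest of every artifact.

All randomness flows from explicit seeds recorded in the manifest, so reruns
are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage

from . import ct_data
from .ct_data import CtMatrix, ExpressionMatrix
from .errors import ValidationError
from .feature_selection import select_differential_genes
from .fuzzy_clustering import DistanceMetric, EUCLIDEAN, project_population
from .model_selection import ModelGrid, model_selection_report, optimize_grid
from .stability import bootstrap_cluster_number, prediction_strength

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    inputs: dict[str, str]            # population id -> Ct table path
    reference: str                    # population whose partition defines clusters
    outdir: str
    comparison: str | None = None     # KS partner; default: first non-reference
    lod_ct: float = 40.0
    clamp_bound: float = 5.0
    pooled_median: bool = True
    alpha: float = 0.01
    max_nondetect_fraction: float | None = None   # gene QC filter, off by default
    k_values: tuple = tuple(range(1, 7))
    m_values: tuple | None = None     # None -> ModelGrid default
    metric: str = "euclidean"
    metric_order: float = 2.0
    n_restarts: int = 5
    seed: int = 0
    blind_labels: bool = True         # strip population labels before clustering
    run_bootstrap: bool = False
    bootstrap_fraction: float = 0.7
    bootstrap_iterations: int = 100
    run_prediction_strength: bool = False
    ps_iterations: int = 20

    def __post_init__(self) -> None:
        if self.reference not in self.inputs:
            raise ValidationError(
                f"reference population {self.reference!r} not among inputs "
                f"{sorted(self.inputs)}")
        if self.comparison is None:
            others = [p for p in self.inputs if p != self.reference]
            if not others:
                raise ValidationError("need at least one non-reference population")
            self.comparison = others[0]
        elif self.comparison not in self.inputs:
            raise ValidationError(f"comparison population {self.comparison!r} unknown")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "k_values" in raw:
            raw["k_values"] = tuple(raw["k_values"])
        if raw.get("m_values") is not None:
            raw["m_values"] = tuple(raw["m_values"])
        return cls(**raw)

    def grid(self) -> ModelGrid:
        if self.m_values is None:
            return ModelGrid(k_values=tuple(self.k_values))
        return ModelGrid(k_values=tuple(self.k_values), m_values=tuple(self.m_values))

    def distance_metric(self) -> DistanceMetric:
        if self.metric == "minkowski":
            return DistanceMetric("minkowski", self.metric_order)
        return DistanceMetric(self.metric)


@dataclass
class RunResult:
    manifest: dict
    manifest_path: Path
    best_k: int
    best_m: float
    selected_genes: list[str]
    occupancies: dict[str, list[float]] = field(default_factory=dict)


def hierarchical_order(e: ExpressionMatrix, cells: list[str] | None = None) -> list[str]:
    """Leaf order of average-linkage (Euclidean) agglomerative clustering of cells."""
    ids = list(e.cell_ids) if cells is None else list(cells)
    if not ids:
        raise ValidationError("no cells to order")
    if len(ids) == 1:
        return ids
    pos = {c: i for i, c in enumerate(e.cell_ids)}
    missing = [c for c in ids if c not in pos]
    if missing:
        raise ValidationError(f"unknown cell id(s): {missing[:5]}")
    X = e.values[[pos[c] for c in ids]]
    Z = linkage(X, method="average", metric="euclidean")
    return [ids[i] for i in leaves_list(Z)]


def export_heatmap_matrix(e: ExpressionMatrix, cell_order: list[str],
                          gene_order: list[str], path) -> None:
    """Write the reordered expression matrix as TSV for external plotting."""
    if sorted(cell_order) != sorted(e.cell_ids):
        raise ValidationError("cell_order is not a permutation of the matrix's cells")
    if sorted(gene_order) != sorted(e.gene_ids):
        raise ValidationError("gene_order is not a permutation of the matrix's genes")
    df = e.to_frame().loc[cell_order, gene_order]
    df.to_csv(path, sep="\t")


def _write(df: pd.DataFrame, path: Path, **kw) -> str:
    df.to_csv(path, sep="\t", **kw)
    return path.name


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full analysis; artifacts land in ``cfg.outdir``.

    Stage failures abort with a stage-named error; artifacts written before a
    failure keep a ``.partial`` marker file alongside them.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {
        "reference": cfg.reference, "comparison": cfg.comparison,
        "lod_ct": cfg.lod_ct, "clamp_bound": cfg.clamp_bound,
        "pooled_median": cfg.pooled_median, "alpha": cfg.alpha,
        "k_values": list(cfg.k_values),
        "m_values": list(cfg.m_values) if cfg.m_values else "default",
        "metric": cfg.metric, "n_restarts": cfg.n_restarts, "seed": cfg.seed,
    }, "artifacts": {}}
    stage = "read"
    try:
        pops: dict[str, CtMatrix] = {}
        for name, path in cfg.inputs.items():
            pops[name] = ct_data.read_ct_table(path, cfg.lod_ct, population_label=name)
        panel = pops[cfg.reference].gene_ids
        for name, m in pops.items():
            if m.gene_ids != panel:
                raise ValidationError(f"population {name!r} gene panel differs "
                                      f"from reference")
        if cfg.max_nondetect_fraction is not None:
            stage = "gene_filter"
            pooled = np.vstack([m.values for m in pops.values()])
            frac = (pooled == cfg.lod_ct).mean(axis=0)
            keep = [g for g, f in zip(panel, frac) if f <= cfg.max_nondetect_fraction]
            if not keep:
                raise ValidationError("no genes survive the nondetect filter")
            pops = {n: m.subset_genes(keep) for n, m in pops.items()}

        stage = "normalize"
        names = list(pops)
        exprs = dict(zip(names, ct_data.normalize_populations(
            [pops[n] for n in names], cfg.clamp_bound, pooled=cfg.pooled_median)))
        if cfg.blind_labels:
            # strip population identity before any clustering stage
            blinded = {n: ExpressionMatrix(e.values, e.cell_ids, e.gene_ids,
                                           "", e.clamp_bound)
                       for n, e in exprs.items()}
        else:
            blinded = exprs
        for n, e in exprs.items():
            manifest["artifacts"][f"expression_{n}"] = _write(
                e.to_frame(), outdir / f"expression_{n}.tsv")

        stage = "feature_selection"
        results = select_differential_genes(blinded[cfg.reference],
                                            blinded[cfg.comparison], cfg.alpha)
        sel_df = pd.DataFrame([{
            "gene": r.gene_id, "ks_statistic": r.ks_statistic, "p_value": r.p_value,
            "p_adjusted": r.p_adjusted, "selected": r.selected} for r in results])
        manifest["artifacts"]["ks_selection"] = _write(
            sel_df, outdir / "ks_selection.tsv", index=False)
        selected = [r.gene_id for r in results if r.selected]
        if not selected:
            raise ValidationError("no genes pass KS selection; nothing to cluster on")

        stage = "optimize"
        ref_e = blinded[cfg.reference].subset_genes(selected)
        best, scores = optimize_grid(ref_e, cfg.grid(), seed=cfg.seed,
                                     metric=cfg.distance_metric(),
                                     n_restarts=cfg.n_restarts)
        manifest["artifacts"]["model_scores"] = _write(
            model_selection_report(scores), outdir / "model_scores.tsv", index=False)
        manifest["artifacts"]["centroids"] = _write(
            pd.DataFrame(best.centroids, columns=selected),
            outdir / "centroids.tsv", index_label="cluster")
        manifest["artifacts"]["memberships_reference"] = _write(
            pd.DataFrame(best.memberships, index=best.cell_ids),
            outdir / f"memberships_{cfg.reference}.tsv", index_label="cell")
        manifest["best_model"] = {"k": best.k, "m": best.m,
                                  "objective": best.objective,
                                  "converged": bool(best.converged)}

        stage = "project"
        occupancies: dict[str, list[float]] = {}
        occ_rows = []
        for name in names:
            e_sel = blinded[name].subset_genes(selected)
            if name == cfg.reference:
                occ = best.occupancy(name)
            else:
                u, occ = project_population(best, e_sel)
                occ = type(occ)(occ.fractions, name, occ.counts)
                manifest["artifacts"][f"memberships_{name}"] = _write(
                    pd.DataFrame(u, index=e_sel.cell_ids),
                    outdir / f"memberships_{name}.tsv", index_label="cell")
            occupancies[name] = [float(f) for f in occ.fractions]
            for c, f in enumerate(occ.fractions):
                occ_rows.append({"population": name, "cluster": c + 1,
                                 "fraction": float(f)})
        manifest["artifacts"]["occupancy"] = _write(
            pd.DataFrame(occ_rows), outdir / "occupancy.tsv", index=False)
        manifest["occupancy"] = occupancies

        if cfg.run_bootstrap:
            stage = "stability_bootstrap"
            rep = bootstrap_cluster_number(ref_e, cfg.grid(), cfg.bootstrap_fraction,
                                           cfg.bootstrap_iterations, seed=cfg.seed,
                                           n_restarts=cfg.n_restarts)
            manifest["bootstrap"] = {
                "k_frequencies": {str(k): v for k, v in rep.k_frequencies.items()},
                "mean_k": rep.mean_k, "sd_k": rep.sd_k}
        if cfg.run_prediction_strength:
            stage = "stability_prediction_strength"
            rep = prediction_strength(ref_e, tuple(cfg.k_values),
                                      n_iterations=cfg.ps_iterations, seed=cfg.seed)
            manifest["prediction_strength"] = {
                "mean_ps": {str(k): v for k, v in rep.mean_ps.items()},
                "chosen_k": rep.chosen_k}

        stage = "heatmap"
        ref_full = exprs[cfg.reference]
        labels = best.hard_labels
        cell_order: list[str] = []
        for c in range(best.k):
            members = [best.cell_ids[i] for i in np.flatnonzero(labels == c)]
            if members:
                cell_order.extend(hierarchical_order(ref_full, members))
        gene_order = list(ref_full.gene_ids)
        manifest["artifacts"]["heatmap_matrix"] = _write_heatmap(
            ref_full, cell_order, gene_order, outdir / "heatmap_matrix.tsv")

        stage = "manifest"
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return RunResult(manifest, manifest_path, best.k, best.m, selected,
                         occupancies)
    except Exception as err:
        marker = outdir / f"{stage}.partial"
        marker.write_text(f"pipeline aborted during stage {stage!r}: {err}\n")
        try:
            raise type(err)(f"[stage: {stage}] {err}") from err
        except TypeError:
            raise RuntimeError(f"[stage: {stage}] {err}") from err


def _write_heatmap(e, cell_order, gene_order, path: Path) -> str:
    export_heatmap_matrix(e, cell_order, gene_order, path)
    return path.name
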