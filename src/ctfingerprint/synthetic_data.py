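"""Seeded generator of single-cell qPCR Ct mixtures.

Emulates the phenomenology of single-cell qPCR panels on sorted stem-cell
populations: per-gene Ct values approximately normal, a minority of genes with
strongly left-skewed Ct laws (transcriptional bursting pushes Ct down),
relative variability that grows with Ct (i.e. with decreasing expression),
and nondetect dropout pinned at the limit-of-detection floor.

A mixture is described by a :class:`PopulationSpec`: each cell is assigned to
one of several subpopulation "archetypes" by weighted draw, then each gene's
Ct is drawn from that archetype's law.  ``make_benchmark_fixture`` builds a
three-archetype, 43-gene, 300-cell trio of populations sharing centroids but
differing in archetype occupancy, mirroring the structure of a CD34lo /
CD34hi / side-population comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ct_data import CtMatrix, DEFAULT_LOD_CT
from .errors import ValidationError

_CT_FLOOR = 1e-2  # values are clipped into (0, lod]; exact 0 is not a valid Ct


@dataclass
class SubpopSpec:
    """One subpopulation archetype: per-gene Gaussian Ct law with dropout.

    ``burst_genes`` lists gene indices drawn instead from a left-skewed law
    ``Ct = mean - LogNormal(0, burst_sigma)`` (bursts increase mRNA, lowering
    Ct, which produces the asymmetric left tail seen for bursty genes).
    """

    weight: float
    gene_means: np.ndarray
    gene_sds: np.ndarray
    dropout_probs: np.ndarray
    burst_genes: tuple[int, ...] = ()
    burst_sigma: float = 1.0

    def __post_init__(self) -> None:
        self.gene_means = np.asarray(self.gene_means, float)
        self.gene_sds = np.asarray(self.gene_sds, float)
        self.dropout_probs = np.asarray(self.dropout_probs, float)
        if not (0.0 <= self.weight <= 1.0):
            raise ValidationError("subpopulation weight must lie in [0, 1]")
        if self.gene_sds.shape != self.gene_means.shape or \
                self.dropout_probs.shape != self.gene_means.shape:
            raise ValidationError("gene_means, gene_sds, dropout_probs must share length")
        if np.any(self.gene_sds <= 0):
            raise ValidationError("gene_sds must be > 0")
        if np.any((self.dropout_probs < 0) | (self.dropout_probs > 1)):
            raise ValidationError("dropout_probs must lie in [0, 1]")
        if any(g < 0 or g >= self.gene_means.size for g in self.burst_genes):
            raise ValidationError("burst gene index out of range")

    @property
    def n_genes(self) -> int:
        return self.gene_means.size


@dataclass
class PopulationSpec:
    """Generative description of a mixture of subpopulations."""

    n_cells: int
    subpopulations: list[SubpopSpec]
    seed: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if not self.subpopulations:
            raise ValidationError("at least one subpopulation required")
        w = np.array([s.weight for s in self.subpopulations])
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"subpopulation weights must sum to 1 (got {w.sum()})")
        genes = {s.n_genes for s in self.subpopulations}
        if len(genes) != 1:
            raise ValidationError("all subpopulations must share the gene panel size")

    @property
    def n_genes(self) -> int:
        return self.subpopulations[0].n_genes


def simulate(spec: PopulationSpec, lod_ct: float = DEFAULT_LOD_CT,
             gene_ids: list[str] | None = None, cell_prefix: str = "cell",
             population_label: str = "synthetic") -> tuple[CtMatrix, np.ndarray]:
    """Draw a Ct matrix and true subpopulation labels from ``spec``.

    Each cell's archetype is a weighted categorical draw; each gene value is
    Gaussian (or burst-law for burst genes), then replaced by ``lod_ct`` with
    the gene's dropout probability, and finally clipped into ``(0, lod_ct]``.
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_cells, spec.n_genes
    weights = np.array([s.weight for s in spec.subpopulations])
    labels = rng.choice(len(spec.subpopulations), size=n, p=weights)
    values = np.empty((n, g))
    for j, sub in enumerate(spec.subpopulations):
        idx = np.flatnonzero(labels == j)
        if idx.size == 0:
            continue
        draw = rng.normal(sub.gene_means, sub.gene_sds, size=(idx.size, g))
        for b in sub.burst_genes:
            draw[:, b] = sub.gene_means[b] - rng.lognormal(0.0, sub.burst_sigma, idx.size)
        drop = rng.random((idx.size, g)) < sub.dropout_probs
        draw[drop] = lod_ct
        values[idx] = draw
    values = np.clip(values, _CT_FLOOR, lod_ct)
    if gene_ids is None:
        gene_ids = [f"G{j + 1:02d}" for j in range(g)]
    cell_ids = [f"{cell_prefix}{i + 1:03d}" for i in range(n)]
    return CtMatrix(values, cell_ids, gene_ids, population_label, lod_ct), labels


# ---------------------------------------------------------------------------
# The three-population benchmark fixture


@dataclass
class BenchmarkFixture:
    """300-cell trio of populations sharing 3 archetypes at different occupancy."""

    cd34lo: CtMatrix
    cd34hi: CtMatrix
    sp: CtMatrix
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    signal_genes: list[str] = field(default_factory=list)
    occupancies: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def populations(self) -> dict[str, CtMatrix]:
        return {"cd34lo": self.cd34lo, "cd34hi": self.cd34hi, "sp": self.sp}


N_GENES = 43
N_SIGNAL = 9
SIGNAL_SHIFT_CT = 2.0  # between-archetype mean separation per signal gene
OCCUPANCY = {
    "cd34lo": (1 / 3, 1 / 3, 1 / 3),
    "cd34hi": (0.04, 0.58, 0.38),
    "sp": (0.68, 0.16, 0.16),
}


def _archetype_params(seed: int):
    """Shared per-gene parameters plus archetype mean offsets on signal genes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    means = rng.uniform(16.0, 30.0, N_GENES)
    means[:N_SIGNAL] = rng.uniform(18.0, 24.0, N_SIGNAL)
    # relative variability rises as expression falls: sd grows with mean Ct
    sds = 0.4 + 0.06 * (means - 16.0)
    # signal genes share a common within-archetype spread so the archetypes are
    # (near-)spherical in clustering space; the variance-with-Ct trend is
    # carried by the 34 noise genes
    sds[:N_SIGNAL] = 0.7
    # dropout rises steeply near the detection limit; negligible for bright genes
    dropout = 1.0 / (1.0 + np.exp(-1.2 * (means - 36.0)))
    burst = tuple(sorted(rng.choice(np.arange(N_SIGNAL, N_GENES), 5, replace=False)))
    arch_means = []
    for a in range(3):
        m = means.copy()
        for s in range(N_SIGNAL):
            # three distinct levels per signal gene, one per archetype,
            # spaced SIGNAL_SHIFT_CT cycles apart (lower Ct = more mRNA)
            m[s] -= SIGNAL_SHIFT_CT * ((a + s) % 3)
        arch_means.append(m)
    return arch_means, sds, dropout, burst


def make_benchmark_fixture(seed: int, n_cells: int = 300,
                           lod_ct: float = DEFAULT_LOD_CT) -> BenchmarkFixture:
    """Build the three-population synthetic benchmark.

    43 genes, 9 of which ("signal genes", G01..G09) carry >= 2-Ct mean shifts
    between three shared archetypes; the remaining 34 are shared-noise genes,
    5 of them bursty.  The three populations draw the same archetypes at
    occupancies ~(1/3, 1/3, 1/3), (0.04, 0.58, 0.38) and (0.68, 0.16, 0.16).
    Deterministic in ``seed``.
    """
    arch_means, sds, dropout, burst = _archetype_params(seed)
    gene_ids = [f"G{j + 1:02d}" for j in range(N_GENES)]
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(OCCUPANCY, np.random.SeedSequence([seed, 31013]).spawn(3))}
    out, labels = {}, {}
    for name, occ in OCCUPANCY.items():
        # burst magnitude kept below the signal genes' between-archetype spread:
        # bursty tails mark a minority of cells without dominating panel variance
        subs = [SubpopSpec(w, arch_means[a], sds, dropout, burst, burst_sigma=0.6)
                for a, w in enumerate(occ)]
        spec = PopulationSpec(n_cells, subs, seeds[name])
        ct, lab = simulate(spec, lod_ct, gene_ids=gene_ids,
                           cell_prefix=f"{name}_", population_label=name)
        out[name], labels[name] = ct, lab
    return BenchmarkFixture(out["cd34lo"], out["cd34hi"], out["sp"], labels,
                            gene_ids[:N_SIGNAL], dict(OCCUPANCY))
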