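import numpy as np
import pytest

import ctfingerprint as cf
from ctfingerprint.synthetic_data import PopulationSpec, SubpopSpec, simulate


def expr(values, clamp=5.0, label="") -> cf.ExpressionMatrix:
    values = np.asarray(values, float)
    return cf.ExpressionMatrix(
        values,
        [f"c{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
        label, clamp,
    )


def homogeneous_ct(seed: int, n_cells: int = 300, n_genes: int = 9) -> cf.CtMatrix:
    """Single-archetype Gaussian population, no bursts, no dropout."""
    rng = np.random.default_rng(seed + 4000)
    sub = SubpopSpec(1.0, rng.uniform(18.0, 24.0, n_genes),
                     np.full(n_genes, 1.0), np.zeros(n_genes))
    ct, _ = simulate(PopulationSpec(n_cells, [sub], seed))
    return ct


def separated3_ct(seed: int, n_cells: int = 300, n_genes: int = 9,
                  shift: float = 2.0, sd: float = 1.0):
    """Three equal-weight archetypes with >= `shift`-Ct mean separation per gene."""
    rng = np.random.default_rng(seed + 4000)
    base = rng.uniform(18.0, 24.0, n_genes)
    subs = []
    for a in range(3):
        m = base.copy()
        for s in range(n_genes):
            m[s] -= shift * ((a + s) % 3)
        subs.append(SubpopSpec(1 / 3, m, np.full(n_genes, sd), np.zeros(n_genes)))
    return simulate(PopulationSpec(n_cells, subs, seed))


@pytest.fixture(scope="session")
def fixture_trio():
    return cf.make_benchmark_fixture(1)


@pytest.fixture(scope="session")
def normalized_trio(fixture_trio):
    lo, hi, sp = cf.normalize_populations(
        [fixture_trio.cd34lo, fixture_trio.cd34hi, fixture_trio.sp])
    return {"cd34lo": lo, "cd34hi": hi, "sp": sp}


@pytest.fixture(scope="session")
def signal_expr(fixture_trio, normalized_trio):
    """Reference population restricted to the 9 signal genes."""
    return normalized_trio["cd34lo"].subset_genes(fixture_trio.signal_genes)


@pytest.fixture(scope="session")
def small_grid():
    return cf.ModelGrid(tuple(range(1, 6)), (1.05, 1.5, 2.0))
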