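import numpy as np
import pytest

from scgrn.data_model import ExpressionMatrix, normalize
from scgrn.synthetic_benchmarks import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_small():
    """Small clustered dataset with planted modules (near-dense reference)."""
    cfg = SimConfig(n_genes=300, n_cells=240, n_clusters=3, n_modules=8,
                    module_size=8, seed=7)
    return simulate(cfg)


@pytest.fixture(scope="session")
def sim_small_norm(sim_small):
    expr, _ = sim_small
    return normalize(expr)


@pytest.fixture(scope="session")
def noise_model(sim_small_norm):
    from scgrn.noise_de import fit_noise_model
    return fit_noise_model(sim_small_norm, seed=7)


@pytest.fixture(scope="session")
def pipeline_small(sim_small):
    """Full inference chain on the small fixture (tree, zmat, table)."""
    from scgrn.pipeline import infer_correlation_table
    expr, _ = sim_small
    return infer_correlation_table(expr, seed=7)


@pytest.fixture(scope="session")
def homogeneous_expr():
    """One homogeneous Poisson population (no structure at all)."""
    rng = np.random.default_rng(11)
    means = rng.gamma(3.0, 6.0, size=250)
    counts = rng.poisson(means[:, None], size=(250, 160)).astype(float)
    genes = np.array([f"G{i}" for i in range(250)], dtype=object)
    cells = np.array([f"C{i}" for i in range(160)], dtype=object)
    return normalize(ExpressionMatrix(genes, cells, counts))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
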