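import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from itlsig import CountMatrix, NormalizedMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def norm_factory():
    """Build a random log-scale NormalizedMatrix (gamma-distributed values)."""

    def make(n_genes=50, n_cells=20, seed=0, prefix="G"):
        r = np.random.default_rng(seed)
        values = r.gamma(2.0, 1.0, size=(n_genes, n_cells))
        genes = [f"{prefix}{i:04d}" for i in range(n_genes)]
        cells = [f"C{i:04d}" for i in range(n_cells)]
        return NormalizedMatrix(values, genes, cells)

    return make


@pytest.fixture
def counts_from_columns():
    """Build a CountMatrix from explicit per-cell count vectors.

    ``columns`` maps cell id -> 1-D integer array over the gene axis; the
    first ``n_mito`` genes are flagged mitochondrial.
    """

    def make(columns: dict, n_genes: int, n_mito: int = 0):
        cells = list(columns)
        values = np.column_stack([np.asarray(columns[c], dtype=np.int64) for c in cells])
        genes = [f"MT-{i}" if i < n_mito else f"G{i:05d}" for i in range(n_genes)]
        mito = np.array([g.startswith("MT-") for g in genes])
        return CountMatrix(values, genes, cells, mito)

    return make


def auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney U / (n_pos * n_neg)); test-side oracle."""
    from scipy.stats import rankdata

    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))
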