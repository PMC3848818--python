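from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dctopo import ConditionPair, ExpressionMatrix, FisherZMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_pair(n_genes: int, n_samples: int, seed: int) -> ConditionPair:
    """Independent-noise condition pair (no planted structure)."""
    rng = np.random.default_rng(seed)
    genes = tuple(f"g{i:03d}" for i in range(n_genes))
    return ConditionPair(
        ExpressionMatrix(genes, tuple(f"a{i}" for i in range(n_samples)),
                         rng.standard_normal((n_genes, n_samples))),
        ExpressionMatrix(genes, tuple(f"b{i}" for i in range(n_samples)),
                         rng.standard_normal((n_genes, n_samples))),
    )


def random_zmatrix(n_genes: int, seed: int, scale: float = 1.0, n: int = 50) -> FisherZMatrix:
    """Symmetric random Fisher-z matrix with zero diagonal."""
    rng = np.random.default_rng(seed)
    z = rng.normal(scale=scale, size=(n_genes, n_genes))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FisherZMatrix(tuple(f"g{i:03d}" for i in range(n_genes)), z, n)


@pytest.fixture
def small_pair() -> ConditionPair:
    return random_pair(12, 20, seed=7)
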