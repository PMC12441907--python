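import numpy as np
import pytest

from grnkit import ExpressionCompendium


@pytest.fixture
def small_compendium() -> ExpressionCompendium:
    rng = np.random.default_rng(42)
    values = rng.uniform(0.1, 10.0, size=(12, 6))
    genes = [f"g{i:02d}" for i in range(12)]
    samples = [f"s{j}" for j in range(6)]
    return ExpressionCompendium(genes, samples, values, normalized=True)


@pytest.fixture
def count_compendium() -> ExpressionCompendium:
    rng = np.random.default_rng(7)
    lam = rng.uniform(2, 60, size=40)
    X = rng.poisson(lam[:, None] * rng.uniform(0.5, 2.0, size=5)[None, :]).astype(float)
    X[X.sum(axis=1) == 0, 0] = 1
    genes = [f"g{i:03d}" for i in range(40)]
    samples = [f"s{j}" for j in range(5)]
    return ExpressionCompendium(genes, samples, X)
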