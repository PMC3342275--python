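import numpy as np
import pytest
from hypothesis import settings

from exonhancer import ExpressionMatrix, simulate_embryos, table1_spec
from exonhancer.vocab import DEFAULT_VOCABULARY

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def vocab():
    return DEFAULT_VOCABULARY


@pytest.fixture(scope="session")
def control_matrix():
    """Simulated minimal-promoter control cohort (161 embryos, 4 rounds)."""
    matrix, _ = simulate_embryos(table1_spec("control", seed=11))
    return matrix


def random_matrix(seed: int, n: int = 50, construct_id: str = "rand") -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 2, size=(n, DEFAULT_VOCABULARY.size), dtype=np.uint8)
    batches = ["b1" if i < n // 2 else "b2" for i in range(n)]
    return ExpressionMatrix(construct_id, data, DEFAULT_VOCABULARY, batch_ids=batches)
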