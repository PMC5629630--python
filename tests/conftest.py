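import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_q(rng, low: float = 0.01, alpha=(2.0, 1.0, 1.0, 1.0)) -> np.ndarray:
    """Random gamete-frequency vector with components >= low, summing to 0.5."""
    q = rng.dirichlet(alpha) * (0.5 - 4 * low) + low
    return q


def coupling_triple_q(r1: float, r2: float) -> np.ndarray:
    """Exact gamete frequencies of a coupling triple with adjacent fractions r1, r2
    under independent crossovers (class order: parental, CO-in-1, CO-in-2, double)."""
    return np.array(
        [(1 - r1) * (1 - r2), r1 * (1 - r2), (1 - r1) * r2, r1 * r2]
    ) / 2.0
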