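import numpy as np
import pytest

from eigendiff import AssayGrouping, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def grouping_3_3():
    return AssayGrouping((1, 2, 3), (4, 5, 6))


@pytest.fixture
def small_matrix(rng):
    """50 genes x 6 assays of log-scale-like values around 5.3."""
    vals = rng.normal(5.3, 0.5, size=(50, 6))
    return ExpressionMatrix(
        vals,
        tuple(f"g{i:02d}" for i in range(50)),
        tuple(f"a{j}" for j in range(6)),
    )


def make_matrix(values, prefix_g="g", prefix_a="a"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ExpressionMatrix(
        values,
        tuple(f"{prefix_g}{i + 1}" for i in range(m)),
        tuple(f"{prefix_a}{j + 1}" for j in range(n)),
    )
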