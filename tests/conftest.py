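import numpy as np
import pytest

from nlnet import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_expr(values) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    return ExpressionMatrix(values,
                            tuple(f"g{i}" for i in range(p)),
                            tuple(f"s{k}" for k in range(n)))


@pytest.fixture
def small_expr(rng) -> ExpressionMatrix:
    return make_expr(rng.standard_normal((6, 7)))
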