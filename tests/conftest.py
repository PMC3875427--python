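import numpy as np
import pytest

from bicnet.core import ExpressionMatrix, PipelineParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_matrix(rng):
    """8 genes x 6 conditions of standard normal noise."""
    vals = rng.normal(size=(8, 6))
    return ExpressionMatrix(
        vals, [f"g{i}" for i in range(8)], [f"c{j}" for j in range(6)]
    )


@pytest.fixture
def noise_matrix(rng):
    """200 genes x 20 conditions of standard normal noise."""
    vals = rng.normal(size=(200, 20))
    return ExpressionMatrix(
        vals,
        [f"g{i:03d}" for i in range(200)],
        [f"c{j:02d}" for j in range(20)],
    )


@pytest.fixture
def default_params():
    return PipelineParams()
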