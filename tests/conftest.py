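import numpy as np
import pytest

from lncarray.iofmt import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 probes x 8 samples (5 case, 3 control), fixed values."""
    rng = np.random.default_rng(42)
    values = rng.uniform(10.0, 1000.0, size=(3, 8))
    return ExpressionMatrix(
        probe_ids=["P1", "P2", "P3"],
        sample_ids=[f"s{i}" for i in range(8)],
        group_labels=["case"] * 5 + ["control"] * 3,
        values=values,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
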