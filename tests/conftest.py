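import numpy as np
import pytest

from rfet.io_core import ExpressionMatrix, SampleRecord, SampleTable


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, fixed values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [5.0, 6.0, 7.0, 8.0],
            [2.5, 2.5, 2.5, 2.5],
        ]
    )
    return ExpressionMatrix(["gA", "gB", "gC"], ["s1", "s2", "s3", "s4"], values)


@pytest.fixture
def small_samples() -> SampleTable:
    return SampleTable(
        [
            SampleRecord("s1", "lineA", "wet", 1, 1),
            SampleRecord("s2", "lineA", "dry", 1, 0),
            SampleRecord("s3", "lineB", "wet", 2, 1),
            SampleRecord("s4", "lineB", "dry", 2, 0),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_matrix(values: np.ndarray, prefix: str = "g") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionMatrix(
        [f"{prefix}{i + 1:03d}" for i in range(g)],
        [f"s{j + 1:02d}" for j in range(n)],
        values,
    )
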