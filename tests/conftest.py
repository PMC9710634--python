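import numpy as np
import pytest

from fedpca import DataMatrix, SpectrumSpec, generate_lowrank, split_by_sizes


def make_matrix(values, prefix="S"):
    """Wrap a plain array into a labeled DataMatrix."""
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return DataMatrix(
        values,
        [f"{prefix}{i}" for i in range(n)],
        [f"G{j}" for j in range(d)],
    )


@pytest.fixture
def small_centered():
    """A tiny centered matrix with a known diagonal covariance: (1/4)A'A =
    diag(2, 0.5)."""
    return make_matrix([[2, 0], [0, 1], [-2, 0], [0, -1]])


@pytest.fixture
def planted():
    """Centered low-rank-plus-noise matrix with well-separated eigengaps."""
    spec = SpectrumSpec(80, 30, [12.0, 8.0, 5.0, 3.0, 2.0], 0.05, seed=11)
    return generate_lowrank(spec)


@pytest.fixture
def planted_partition(planted):
    return split_by_sizes(planted, [40, 25, 10, 4, 1])
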