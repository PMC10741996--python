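import numpy as np
import pytest

from rfgsea import ExpressionMatrix, GeneSet


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    genes = tuple(f"G{i}" for i in range(8))
    samples = tuple(f"S{j}" for j in range(6))
    return ExpressionMatrix(genes, samples, rng.normal(size=(8, 6)))


@pytest.fixture
def small_set() -> GeneSet:
    return GeneSet(name="demo", genes=("G1", "G3", "G5"))


def two_group_matrix(seed=0, n_samples=60, n_features=20, separation=10.0):
    """Two Gaussian sample groups separated along the first feature axis
    by ``separation`` standard deviations; returns (matrix, truth labels)."""
    rng = np.random.default_rng(seed)
    truth = np.array([0] * (n_samples // 2) + [1] * (n_samples - n_samples // 2))
    centers = np.zeros((2, n_features))
    centers[1, 0] = separation
    X = centers[truth] + rng.normal(size=(n_samples, n_features))
    genes = tuple(f"F{i}" for i in range(n_features))
    samples = tuple(f"S{j}" for j in range(n_samples))
    return ExpressionMatrix(genes, samples, X.T), truth
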