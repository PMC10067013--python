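import numpy as np
import pytest

from cytobench import ExpressionMatrix, LabelVector, default_model, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blobs_200(rng):
    """Three well-separated Gaussian blobs, 200 cells in 5 dimensions."""
    centers = np.array(
        [[0.0] * 5, [8.0] + [0.0] * 4, [0.0, 8.0, 8.0, 0.0, 0.0]]
    )
    sizes = [70, 70, 60]
    X = np.vstack(
        [rng.normal(c, 0.5, size=(s, 5)) for c, s in zip(centers, sizes)]
    )
    labels = np.repeat([0, 1, 2], sizes)
    return X, labels


@pytest.fixture
def small_sample():
    """A 500-cell simulated sample with 4 types in 2 trees."""
    model = default_model(4, 12, n_trees=2, seed=7)
    return simulate(model, 500, seed=11)


@pytest.fixture
def expr_small(blobs_200):
    X, labels = blobs_200
    names = [f"m{i}" for i in range(X.shape[1])]
    return ExpressionMatrix(values=X, marker_names=names), LabelVector(labels=labels)
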