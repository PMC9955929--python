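import numpy as np
import pytest

from kplsmwmr import FeatureMatrix, LabelVector, SynthConfig, generate


@pytest.fixture(scope="session")
def default_dataset():
    """The canonical synthetic benchmark: 300 x 103, three balanced classes."""
    return generate(SynthConfig(seed=0))


@pytest.fixture()
def tiny_dataset():
    """8 samples, 2 features, 2 classes — small enough for hand enumeration."""
    values = np.array(
        [
            [0.0, 1.0],
            [0.2, 0.4],
            [0.1, 0.9],
            [0.3, 0.2],
            [1.0, 0.5],
            [0.9, 0.1],
            [1.1, 0.8],
            [0.8, 0.3],
        ]
    )
    X = FeatureMatrix(values, ["f1", "f2"], [f"s{i}" for i in range(8)])
    y = LabelVector(np.array(["a", "a", "a", "a", "b", "b", "b", "b"]))
    return X, y


@pytest.fixture()
def duplicated_dataset():
    """An informative column duplicated exactly, plus two uncorrelated ones.

    Built so redundancy-aware selection must skip the duplicate: d1 == f1
    (|r| = 1) while g1 and g2 are label-free independent noise (|r| ~ 0),
    so at small alpha the duplicate always loses to an uncorrelated
    candidate.
    """
    rng = np.random.default_rng(7)
    n = 60
    labels = np.repeat(["a", "b", "c"], n // 3)
    base = np.repeat([0.0, 5.0, 10.0], n // 3)
    f1 = base + rng.normal(0, 0.5, n)
    g1 = rng.normal(0, 1.0, n)
    g2 = rng.normal(0, 1.0, n)
    values = np.column_stack([f1, f1.copy(), g1, g2])
    X = FeatureMatrix(values, ["f1", "d1", "g1", "g2"], [str(i) for i in range(n)])
    return X, LabelVector(labels)
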