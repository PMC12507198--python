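import numpy as np
import pandas as pd
import pytest

from habshift import (
    GridSpec,
    SyntheticTruth,
    compute_true_suitability,
    generate_env_stack,
)
from habshift.occurrences import SampleMatrix


@pytest.fixture(scope="session")
def spec80():
    return GridSpec(80, 80)


@pytest.fixture(scope="session")
def truth():
    return SyntheticTruth(seed=11)


@pytest.fixture(scope="session")
def stack80(truth, spec80):
    return generate_env_stack(truth, spec80)


@pytest.fixture(scope="session")
def suitability80(stack80, truth):
    return compute_true_suitability(stack80, truth)


def make_samples(n=200, p=5, seed=0, informative=0):
    """Random feature table with an optional informative column driving labels."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"v{i}" for i in range(p)]
    )
    if informative is None:
        y = rng.integers(0, 2, size=n)
    else:
        logit = 3.0 * X.iloc[:, informative].to_numpy() + rng.normal(0, 0.5, n)
        y = (logit > 0).astype(int)
    if y.min() == y.max():  # ensure both classes
        y[0] = 1 - y[0]
    return SampleMatrix(X, y, np.arange(n))
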