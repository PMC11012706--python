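import numpy as np
import pytest

from profwise import ExpressionMatrix, TargetVector
from profwise.synthetic import SyntheticSpec, generate


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 features with simple values."""
    return ExpressionMatrix(
        ["s1", "s2", "s3"],
        ["fA", "fB"],
        np.array([[1.0, 8.0], [2.0, 4.0], [4.0, 2.0]]),
    )


@pytest.fixture
def binary_target():
    return TargetVector(
        "binary", np.array(["methylated", "unmethylated", "methylated"])
    )


@pytest.fixture(scope="session")
def small_classification():
    """A quick 60 x 150 classification instance with 5 planted groups."""
    spec = SyntheticSpec(
        n_samples=60,
        n_features=150,
        n_informative=5,
        n_redundant_per_informative=1,
        effect_size=1.5,
        seed=7,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def class_report(small_classification):
    """A completed classification run on the small instance (shared: the
    pipeline is deterministic, so read-only tests can reuse one report)."""
    from profwise import ProfwiseConfig, run_profwise
    from profwise.selectors import MrmrConfig

    matrix, target, _ = small_classification
    cfg = ProfwiseConfig(task="classification", mrmr=MrmrConfig(n_select=15))
    return run_profwise(matrix, target, cfg)


@pytest.fixture(scope="session")
def reg_report(small_regression):
    from profwise import ProfwiseConfig, run_profwise
    from profwise.selectors import MrmrConfig

    matrix, target, _ = small_regression
    cfg = ProfwiseConfig(task="regression", mrmr=MrmrConfig(n_select=15))
    return run_profwise(matrix, target, cfg)


@pytest.fixture(scope="session")
def small_regression():
    spec = SyntheticSpec(
        n_samples=60,
        n_features=150,
        n_informative=5,
        n_redundant_per_informative=1,
        effect_size=1.0,
        task="regression",
        seed=7,
    )
    return generate(spec)
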