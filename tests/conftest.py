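import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from traitnet import TraitMatrix


@pytest.fixture
def tiny_tm() -> TraitMatrix:
    """Three species, two families, three traits; the worked hand example."""
    return TraitMatrix(
        species_ids=["s1", "s2", "s3"],
        families=["famA", "famA", "famB"],
        trait_names=["t1", "t2", "t3"],
        A=[[1, 1, 0], [1, 0, 1], [0, 1, 1]],
    )


@pytest.fixture
def exclusive_tm() -> TraitMatrix:
    """Five species over two one-of-k categories."""
    return TraitMatrix(
        species_ids=[f"s{i}" for i in range(1, 6)],
        families=["famA", "famA", "famB", "famB", "famC"],
        trait_names=["x", "y"],
        A=[[1, 0], [1, 0], [0, 1], [0, 1], [1, 0]],
        exclusive=True,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
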