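import numpy as np
import pytest

from slicesurv.survival_head import T_MAX, SurvivalDistribution, SurvivalRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_distribution(rng: np.random.Generator) -> SurvivalDistribution:
    y = rng.dirichlet(np.ones(T_MAX))
    return SurvivalDistribution(y)


def random_record(rng: np.random.Generator) -> SurvivalRecord:
    return SurvivalRecord(s=int(rng.integers(1, T_MAX + 1)), k=int(rng.integers(0, 2)))


@pytest.fixture
def make_distribution():
    return random_distribution


@pytest.fixture
def make_record():
    return random_record
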