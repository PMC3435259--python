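import numpy as np
import pytest

from editnet.core import Cohort, PatternCounts, SiteSet
from editnet.enumeration import enumerate_classes, enumerate_dags


@pytest.fixture(scope="session")
def sites5() -> SiteSet:
    return SiteSet()


@pytest.fixture(scope="session")
def dags3():
    return enumerate_dags(3)


@pytest.fixture(scope="session")
def classes3():
    return enumerate_classes(3)


@pytest.fixture(scope="session")
def dags5():
    return enumerate_dags(5)


@pytest.fixture(scope="session")
def classes5():
    return enumerate_classes(5)


@pytest.fixture
def toy_counts2() -> PatternCounts:
    """S=2 toy dataset: two 00 reads and two 11 reads."""
    return PatternCounts("toy", [2, 0, 0, 2])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def random_counts(rng: np.random.Generator, S: int, N: int = 1000,
                  individual_id: str = "rand") -> PatternCounts:
    probs = rng.dirichlet(np.ones(1 << S))
    return PatternCounts(individual_id, rng.multinomial(N, probs))


@pytest.fixture
def small_cohort(sites5) -> Cohort:
    """Three individuals, two groups, S=5."""
    rng = np.random.default_rng(7)
    inds = [random_counts(rng, 5, 500, f"i{k}") for k in range(3)]
    group = {"i0": "ctrl", "i1": "ctrl", "i2": "case"}
    return Cohort(sites=sites5, individuals=inds, group=group)
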