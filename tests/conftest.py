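import numpy as np
import pytest

from phyloarb import Tree, FixtureSpec, make_study_fixture


@pytest.fixture
def quartet() -> Tree:
    return Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def cherry() -> Tree:
    return Tree.from_newick("(A:0.5,B:0.5);")


@pytest.fixture(scope="session")
def study_bundle():
    """Default-sized synthetic study bundle, shared across tests."""
    return make_study_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced bundle for file-level pipeline tests."""
    return make_study_fixture(FixtureSpec(seed=2, group_sizes=(2, 3, 4, 8),
                                          n_discrete=3, n_continuous=2,
                                          missing_fraction=0.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
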