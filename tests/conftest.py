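import numpy as np
import pytest

from embryomorph import SimParams, builtin_scheme, simulate_dataset

EXPERIENCED = ("obs1", "obs2", "obs3")


@pytest.fixture(scope="session")
def scheme():
    return builtin_scheme()


@pytest.fixture(scope="session")
def default_sim():
    """One default-design dataset plus ground truth, shared read-only."""
    return simulate_dataset(SimParams(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def single_age_params(**kw) -> SimParams:
    """A cheap one-age design used by replicate studies (E10.5 analysed)."""
    kw.setdefault("n_specimens", (10, 1, 1))
    return SimParams(**kw)
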