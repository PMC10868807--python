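import pytest
from hypothesis import HealthCheck, settings

from ssa_spectra import ErrorModel, LibraryDesign, make_reference_pair

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def refs():
    """Default synthetic F/A repeat pair and its variant map."""
    return make_reference_pair(seed=1)


@pytest.fixture(scope="session")
def pair(refs):
    return refs[0]


@pytest.fixture(scope="session")
def vmap(refs):
    return refs[1]


@pytest.fixture()
def small_design():
    """A 12-colony library with modest depth, for fast unit tests.

    Depth is floored at 20 reads: the exact-recovery guarantee of the
    19% duplex rule holds from that depth upward.
    """
    return LibraryDesign.default(
        seed=2, n_colonies=12, depth_mean=40.0, depth_sd=15.0, depth_min=20
    )


@pytest.fixture()
def no_error():
    return ErrorModel()
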