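import pytest
from hypothesis import HealthCheck, settings

from hivcea import CostUtilityModel, paper_fixture
from hivcea.psa import DEFAULT_SEED

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """The published input set."""
    return paper_fixture()


@pytest.fixture(scope="session")
def model(params):
    return CostUtilityModel(params)


@pytest.fixture(scope="session")
def fitted(model):
    return model.fit()


@pytest.fixture(scope="session")
def psa_default(model):
    """The full-size PSA shared by probabilistic and VOI checks."""
    return model.psa(n=10_000, seed=DEFAULT_SEED)
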