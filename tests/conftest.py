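import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cleaverep import CatalyticParams, ChemostatParams, fixed_point_census

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

np.seterr(all="ignore")  # transient over/underflow inside solver steps is expected


@pytest.fixture(scope="session")
def chem():
    """Headline chemostat conditions: m0=100, delta=1, r=1, beta0=0.015."""
    return ChemostatParams()


@pytest.fixture(scope="session")
def p6(chem):
    return CatalyticParams(chemostat=chem, beta=6.0)


@pytest.fixture(scope="session")
def p10(chem):
    return CatalyticParams(chemostat=chem, beta=10.0)


@pytest.fixture(scope="session")
def p18(chem):
    return CatalyticParams(chemostat=chem, beta=18.0)


@pytest.fixture(scope="session")
def census10(p10):
    return fixed_point_census(p10)


@pytest.fixture(scope="session")
def coop10(census10):
    return next(fp for fp in census10 if fp.kind == "cooperative")
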