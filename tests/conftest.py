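import pytest

from ceqpbpk import DosingRegimen, default_params


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def phys(params):
    return params[0]


@pytest.fixture(scope="session")
def chem(params):
    return params[1]


@pytest.fixture(scope="session")
def single_dose():
    """Label single dose: 2 mg/kg IM."""
    return DosingRegimen(2.0)
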