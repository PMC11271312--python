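import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def human_insulin():
    from chainsplit.analyte import build_analogue

    return build_analogue({"name": "human_insulin"})


@pytest.fixture(scope="session")
def icodec():
    from chainsplit.analyte import get_analogue

    return get_analogue("icodec")


@pytest.fixture(scope="session")
def analogue_library():
    from chainsplit.analyte import load_analogue_library

    return load_analogue_library()


@pytest.fixture(scope="session")
def toy_disulphide_structure():
    from chainsplit.synthdata import build_toy_structure

    return build_toy_structure("buried-vs-exposed-disulphide")
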