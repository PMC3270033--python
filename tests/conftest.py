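from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def figure2():
    from walker.simdata import figure2_fixture

    return figure2_fixture()


@pytest.fixture(scope="session")
def tpm2():
    from walker.simdata import tpm2_fixture

    return tpm2_fixture()
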