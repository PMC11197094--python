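import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ctx():
    from radscav.kinetics import KineticContext

    return KineticContext()


@pytest.fixture(scope="session")
def diffusion():
    from radscav.kinetics import DiffusionInputs

    return DiffusionInputs()


@pytest.fixture(scope="session")
def scavenging_fixture():
    from radscav.datasets import load_fixture

    return load_fixture("table1")


@pytest.fixture(scope="session")
def galangin():
    from radscav.datasets import galangin_ladder, hydroperoxyl_pair

    return galangin_ladder(), hydroperoxyl_pair()
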