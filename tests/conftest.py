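import logging

import pytest

from mitoscribe.classify import classify_all
from mitoscribe.fixtures import sericothrips_annotation
from mitoscribe.simulate import default_scenario, simulate_transcripts

logging.getLogger("mitoscribe").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def refined():
    return sericothrips_annotation(refined=True)


@pytest.fixture(scope="session")
def dna():
    return sericothrips_annotation(refined=False)


@pytest.fixture(scope="session")
def sim():
    """One default-scenario simulation shared by read-only tests."""
    scenario = default_scenario()
    result = simulate_transcripts(scenario)
    return scenario, result


@pytest.fixture(scope="session")
def classified(sim, refined):
    _, result = sim
    return classify_all(result.transcripts, refined, tol=3)
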