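import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1_deletions():
    from tadpose.fixtures import validation_deletions

    return validation_deletions()


@pytest.fixture(scope="session")
def table2_genes():
    from tadpose.fixtures import candidate_genes

    return candidate_genes()


#: Printed presence/absence pattern: True = gene present, False = deleted,
#: per patient PMS 1..5 in deletion-size order.
PRESENCE_PATTERN = {
    "ADSL": (True, True, True, True, True),
    "EP300": (True, True, True, True, True),
    "TNFRSF13C": (True, True, True, True, True),
    "NAGA": (True, True, True, True, True),
    "A4GALT": (False, False, True, True, True),
    "TRMU": (False, False, False, True, True),
    "TUBGCP6": (False, False, False, False, True),
    "SBF1": (False, False, False, False, True),
    "ARSA": (False, False, False, False, True),
}


@pytest.fixture(scope="session")
def presence_pattern():
    return PRESENCE_PATTERN
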