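import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_fixture():
    """3 genera x 2 species reference panel with taxonomy and phylogeny."""
    from vagitax.synthetic_data import make_reference_fixture

    return make_reference_fixture(n_genera=3, species_per_genus=2, seed=11)


@pytest.fixture(scope="session")
def mock_fixture():
    """10-genus single-species mock-community panel (the validation layout)."""
    from vagitax.synthetic_data import make_reference_fixture

    return make_reference_fixture(n_genera=10, species_per_genus=1, seed=1)


@pytest.fixture(scope="session")
def confusable_pair():
    from vagitax.synthetic_data import make_v34_confusable_pair

    return make_v34_confusable_pair(seed=5)
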