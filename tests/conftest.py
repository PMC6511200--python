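import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_profiles():
    """Packaged steady-state FAME table keyed by condition label."""
    from algafuel.io import load_reference_profiles

    return {p.condition: p for p in load_reference_profiles()}


@pytest.fixture(scope="session")
def reference_class_sums():
    from algafuel.io import load_reference_class_sums

    return load_reference_class_sums()


@pytest.fixture(scope="session")
def reference_property_table():
    from algafuel.io import load_reference_property_table

    return load_reference_property_table()
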