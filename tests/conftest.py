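import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ionbind",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ionbind")


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small planted-signal dataset shared by protocol-level tests."""
    from ionbind import SimulationConfig, generate

    config = SimulationConfig(
        n_chains=12, length_range=(40, 70), binding_rate=0.12, seed=7
    )
    return generate(config)
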