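import pytest
from hypothesis import HealthCheck, settings

from mitoarch.simulate import (REPLICA_KEYS, load_architecture_spec,
                               replicate_architecture)

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

AV, HN, OM = REPLICA_KEYS


@pytest.fixture(scope="session")
def specs():
    """Packaged architecture specs for the three skipper mitogenomes."""
    return {key: load_architecture_spec(key) for key in REPLICA_KEYS}


@pytest.fixture(scope="session")
def replicas():
    """Synthesized genomes realizing the three published architectures."""
    return {key: replicate_architecture(key, seed=7) for key in REPLICA_KEYS}
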