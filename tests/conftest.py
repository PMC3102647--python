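import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def unconfined_ensemble():
    """A mid-size lattice-walk ensemble shared across read-only tests."""
    from chromofold import fjc_ensemble

    return fjc_ensemble(1024, mode="unconfined", n_chains=128, seed=2024)
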