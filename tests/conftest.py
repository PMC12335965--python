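import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gfcpm

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_scheme():
    """12-node scheme spanning 4 networks."""
    return gfcpm.make_parcellation(
        12, network_sizes={"SMN": 4, "VN": 3, "DMN": 3, "SAN": 2}, seed=0
    )


@pytest.fixture(scope="session")
def small_cohort(tiny_scheme):
    """Deterministic 12-subject cohort with a planted link on 4 edges."""
    return gfcpm.generate_cohort(
        n_subjects=12,
        scheme=tiny_scheme,
        n_signal_edges=4,
        effect_size=0.5,
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
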