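import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def n1_table():
    from gtna.node_atlas import packaged_node_table

    return packaged_node_table("N1")


@pytest.fixture(scope="session")
def n2_table():
    from gtna.node_atlas import packaged_node_table

    return packaged_node_table("N2")


@pytest.fixture()
def rng():
    return np.random.default_rng(20130429)


@pytest.fixture(scope="session")
def small_cohort():
    """Four subjects per group on a 12-node network; session-scoped for reuse."""
    from gtna.synthetic_data import default_cohort

    return default_cohort(n_nodes=12, master_seed=11, n_per_group=4)
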