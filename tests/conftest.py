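import pytest
from hypothesis import HealthCheck, settings

import streamhealth as sh
from streamhealth.dag_filter import FilterSpec, modified_index_table
from streamhealth.indices import compute_index_table

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_bundle():
    """One default synthetic bundle shared by the read-only tests."""
    return sh.simulate(sh.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def sim_tables(sim_bundle):
    """(aligned bundle, original index table, modified index table)."""
    aligned = sim_bundle.aligned()
    orig = compute_index_table(aligned)
    mod = modified_index_table(aligned, FilterSpec())
    return aligned, orig, mod


@pytest.fixture(scope="session")
def schemes():
    return sh.load_schemes()
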