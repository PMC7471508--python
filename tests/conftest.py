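import pytest
from hypothesis import settings

from t2c.synthetic import SimulationSpec, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_spec() -> SimulationSpec:
    """The shipped locus-like simulation defaults, seed 1."""
    return SimulationSpec(seed=1)


@pytest.fixture(scope="session")
def sim_manifest(tmp_path_factory, default_spec):
    """One full synthetic experiment on disk, shared across tests."""
    out = tmp_path_factory.mktemp("sim_default")
    return simulate(default_spec, out)
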