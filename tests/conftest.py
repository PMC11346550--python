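import pytest
from hypothesis import HealthCheck, settings

from circbalance.simulate import SimConfig, simulate_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study (seed 0) shared by heavier tests."""
    return simulate_study(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_sim_dir(tmp_path_factory):
    """A small study written to disk, for I/O round-trip and pipeline tests."""
    out = tmp_path_factory.mktemp("small_sim")
    result = simulate_study(SimConfig(seed=7, n_genes=120), out)
    return result, out
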