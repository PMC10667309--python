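import pytest

from hicphage import SimulationConfig, simulate_community


@pytest.fixture(scope="session")
def small_config():
    """A small community that still exercises every pipeline stage."""
    return SimulationConfig(n_hosts=15, n_phages=20, n_replicates=3, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_community(small_config)


@pytest.fixture(scope="session")
def small_sim_dir(small_sim, tmp_path_factory):
    truth, dataset = small_sim
    path = tmp_path_factory.mktemp("smallsim")
    dataset.to_directory(path, truth=truth)
    return path


@pytest.fixture(scope="session")
def default_sim_dir(tmp_path_factory):
    """The documented default community (100 hosts, 150 phages, 3+3, seed 1)."""
    truth, dataset = simulate_community(SimulationConfig(seed=1))
    path = tmp_path_factory.mktemp("defaultsim")
    dataset.to_directory(path, truth=truth)
    return path
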