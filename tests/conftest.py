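import pytest

from varprior.pipeline import load_dataset, run_all
from varprior.simulate import SimConfig, make_worked_fixture, simulate_dataset


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """One default-config dataset shared across tests (seed 1)."""
    root = tmp_path_factory.mktemp("sim_default")
    cfg = SimConfig(seed=1)
    paths, truth = simulate_dataset(cfg, root)
    return cfg, root, truth


@pytest.fixture(scope="session")
def default_run(default_sim):
    cfg, root, truth = default_sim
    dataset = load_dataset(root)
    result = run_all(dataset, seed=1)
    return truth, dataset, result


@pytest.fixture(scope="session")
def limit_sim(tmp_path_factory):
    """signal_strength=1, background_rate=0, exactly one causal per locus."""
    root = tmp_path_factory.mktemp("sim_limit")
    cfg = SimConfig(
        seed=7,
        signal_strength=1.0,
        background_rate=0.0,
        frac_causal=1 / 25,  # n_loci causal variants, one per locus
    )
    paths, truth = simulate_dataset(cfg, root)
    dataset = load_dataset(root)
    result = run_all(dataset, seed=7)
    return cfg, truth, result


@pytest.fixture(scope="session")
def worked_fixture(tmp_path_factory):
    root = tmp_path_factory.mktemp("worked")
    cfg, paths, truth = make_worked_fixture(root)
    dataset = load_dataset(root)
    result = run_all(dataset, seed=0)
    return truth, result
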