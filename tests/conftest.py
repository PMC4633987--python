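import numpy as np
import pytest

import chromdyn as cd


@pytest.fixture(scope="session")
def default_sim():
    return cd.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_sim):
    genome = cd.simulate_genome(default_sim)
    return cd.simulate_truth(genome, default_sim)


@pytest.fixture(scope="session")
def pipeline_result(default_sim):
    """One full end-to-end run on the default synthetic dataset, shared by
    recovery and acceptance tests."""
    return cd.run_pipeline(default_sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_genome():
    return cd.GenomeSpec(("chrA", "chrB"), (20_000, 10_000))


def make_track(grid, values, mark="", stage=""):
    return cd.EnrichmentTrack(grid=grid, values=np.asarray(values, dtype=float), mark=mark, stage=stage)
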