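import pathlib

import pytest
from hypothesis import HealthCheck, settings

from mirmint.simulate import SimulationConfig, generate_dataset, make_design

settings.register_profile(
    "mirmint",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("mirmint")

DATA_DIR = pathlib.Path(__file__).parent / "data"
REPO_ROOT = pathlib.Path(__file__).parents[1]


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study keeping the full structure, for fast tests."""
    return SimulationConfig(
        n_probes=400,
        n_genes=300,
        n_mirs=40,
        n_de_mirs=6,
        targets_per_mir=(5, 15),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_run(small_dataset):
    """Default-threshold pipeline stages run in memory on the small dataset."""
    from mirmint.pipeline import RunConfig, run_stages

    return run_stages(
        small_dataset.genes,
        small_dataset.mirs,
        small_dataset.design,
        small_dataset.predictions,
        RunConfig(),
    )
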