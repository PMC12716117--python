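import logging

import pytest

import proformquant as pq
from proformquant.pipeline import PipelineConfig, run_pipeline

logging.getLogger("proformquant").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario synthetic study (6 donors x 2 conditions x 3 CVs)."""
    return pq.simulate(pq.SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_sim):
    """Full pipeline run on the default synthetic study."""
    cfg = PipelineConfig(seed=1)
    return run_pipeline(cfg, frames=list(default_sim.tables.values()),
                        design=default_sim.design, write=False)


@pytest.fixture(scope="session")
def region_map():
    return pq.load_region_map()


@pytest.fixture(scope="session")
def mod_table():
    return pq.load_mod_table()
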