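import dataclasses

import numpy as np
import pytest

import sepalsim as ss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_noise():
    return ss.DivisionNoise()


def make_cell(
    *,
    area=100.0,
    length=None,
    width=None,
    phase="patterning",
    ploidy=2,
    patterning_cycle=0,
    cycle_duration=24.0,
    stomatal_rounds_done=0,
):
    if length is None and width is None:
        length, width = 2.0 * np.sqrt(area / 2.0), np.sqrt(area / 2.0)
    return ss.CellState(
        cell_id=0,
        parent_id=None,
        birth_time=0.0,
        area=length * width,
        length=length,
        width=width,
        column=0,
        phase=phase,
        ploidy=ploidy,
        patterning_cycle=patterning_cycle,
        cycle_duration=cycle_duration,
        stomatal_rounds_done=stomatal_rounds_done,
    )


@pytest.fixture
def cell_factory():
    return make_cell


@pytest.fixture(scope="session")
def wildtype_config():
    return ss.make_config("wildtype", seed=101)


@pytest.fixture(scope="session")
def wildtype_run(wildtype_config):
    """One full wild-type simulation shared across tests."""
    return ss.run_simulation(wildtype_config)


@pytest.fixture(scope="session")
def noise_free_run():
    cfg = ss.make_config(
        "wildtype",
        seed=7,
        noise_free=True,
        cycle_dist=dataclasses.replace(ss.CycleTimeDistribution(), sd_hours=0.0),
    )
    return ss.run_simulation(cfg)
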