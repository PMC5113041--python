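import pytest

import wormabm as w
from wormabm.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def det_fixture():
    """4 founders, 2 generations, no timing noise: 28 cells, 16 leaves."""
    return make_fixture(FixtureSpec(n_founders=4, generations=2, sd_level=0.0, rng_seed=3))


@pytest.fixture(scope="session")
def det_tables(det_fixture):
    return w.TableTriple.from_entries(
        det_fixture.schedule, det_fixture.directions, det_fixture.targets
    )


@pytest.fixture(scope="session")
def det_run(det_fixture, det_tables):
    """A full deterministic run of the 28-cell fixture."""
    config = w.SimulationConfig(end_time=det_fixture.horizon_seconds, rng_seed=1)
    return w.run(det_fixture.initial_cells, det_tables, config)


@pytest.fixture(scope="session")
def noisy_fixture():
    """Same lineage, but with per-cell timing SDs written to the table."""
    return make_fixture(FixtureSpec(n_founders=4, generations=2, sd_level=0.5, rng_seed=3))
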