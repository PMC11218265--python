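import logging

import pytest

from vepbench.synthetic_cohort import SimulationConfig, simulate_cohort, write_fixture

logging.getLogger("vepbench").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial cohort: 800 participants, a 60- and a 30-variant gene."""
    cfg = SimulationConfig(n_participants=800, variants_per_gene=(60, 30), seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_cohort):
    out = tmp_path_factory.mktemp("fixture")
    write_fixture(small_cohort, out)
    return out
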