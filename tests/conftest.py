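"""Shared fixtures: a small structured synthetic cohort with known truth.

Everything is generated at test time from fixed seeds; nothing is read
from disk except what the tests themselves write to tmp paths.
"""

import numpy as np
import pytest

from pgseval.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_scoring_files,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_samples={"North": 250, "Center": 90, "South": 110, "Sardinia": 50},
        n_variants=1000,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_cohort(small_config):
    """(GenotypeMatrix, cohort DataFrame, TruthRecord) for the shared cohort."""
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def score_files(small_config, sim_cohort):
    geno, _, truth = sim_cohort
    return simulate_scoring_files(small_config, truth, geno)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_config):
    """A full on-disk fixture set written once per session."""
    from pgseval.simulate import write_fixture_set

    outdir = tmp_path_factory.mktemp("fixtures")
    manifest = write_fixture_set(outdir, small_config)
    return outdir, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(20240926)
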