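import pytest

from droughtmem import traits, stm
from droughtmem.config import NoiseModel, SimConfig
from droughtmem.pipeline import run_analysis
from droughtmem.simulate import generate_experiment

ZERO_NOISE = NoiseModel(0, 0, 0, 0, 0)


@pytest.fixture(scope="session")
def panel_exact():
    """Full-size zero-noise experiment: 59 accessions x 2 treatments x 4 reps."""
    cfg = SimConfig(n_accessions=59, n_replicates=4, seed=11,
                    measurement_noise=ZERO_NOISE)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def panel_exact_profiles(panel_exact):
    summary = traits.summarize(panel_exact.tables)
    return stm.compute_profiles(summary).set_index("accession_id")


@pytest.fixture(scope="session")
def small_noisy():
    """Small default-noise experiment used by multivariate/CLI tests."""
    cfg = SimConfig(n_accessions=20, seed=7)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def small_noisy_result(small_noisy):
    return run_analysis(small_noisy.tables)
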