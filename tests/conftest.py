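import pytest

from repstab.repeat_finder import DetectionParams
from repstab.synthetic_data import SimulationConfig, generate_cohort, generate_reference


@pytest.fixture(scope="session")
def detect20() -> DetectionParams:
    """Detection thresholds with units capped at 20 bp (the synthetic
    cohorts plant units of at most 6 bp)."""
    return DetectionParams(max_unit_length=20)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=12, n_patients=4, promoter_length=300,
                            exon_length_range=(200, 300), n_msi_patients=1,
                            seed=41)


@pytest.fixture(scope="session")
def small_cohort(small_config, detect20):
    reference = generate_reference(small_config, detect20)
    return generate_cohort(reference, detection=detect20)
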