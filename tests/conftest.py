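import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_caps():
    from capscape.match import enumerate_caps

    return enumerate_caps()


@pytest.fixture(scope="session")
def reference_matrix():
    from capscape.match import load_reference_detection_matrix

    return load_reference_detection_matrix()


@pytest.fixture(scope="session")
def assigned_rows(reference_matrix):
    """Rows of the detection matrix with an assigned (non-Yn) structure."""
    return reference_matrix.dropna(subset=["calculated_mass"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated genome shared across tests (seed fixed)."""
    from capscape.simulate import SimulationConfig, gen_genome_and_annotation

    config = SimulationConfig(seed=11, reads_per_library=600)
    return config, gen_genome_and_annotation(config)
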