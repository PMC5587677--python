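import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    from lncwheat.synthetic_data import GeneratorConfig

    return GeneratorConfig(seed=42, n_coding=60, n_lncrna=40, n_contaminant=12,
                           n_precursors=8, n_as_loci=30)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One shared synthetic dataset for read-only tests."""
    from lncwheat import synthetic_data as sim

    transcripts, truth = sim.generate_transcriptome(small_config)
    return transcripts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
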