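import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from mirsnpmech import pipeline_report, synthetic_data

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (seed 1): all mechanisms planted, six
    verified-inert control SNPs."""
    return synthetic_data.generate_dataset(synthetic_data.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """Full pipeline run on the default synthetic study."""
    inputs = pipeline_report.PipelineInputs.from_dataset(default_dataset)
    return pipeline_report.run_pipeline(inputs)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_panel(columns, positions=None, chrom="chr1"):
    """HaplotypePanel from an explicit list of 0/1 columns."""
    from mirsnpmech.ld_toolkit import HaplotypePanel
    h = np.array(columns, dtype=np.int8).T
    n = h.shape[1]
    if positions is None:
        positions = np.arange(n) * 1000
    return HaplotypePanel([f"s{i}" for i in range(n)], h, [chrom] * n,
                          np.asarray(positions))
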