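import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def crc_tables():
    """Bundled verification count tables keyed by SNP id."""
    from poolgwas.datasets import load_crc_verification_counts

    return {t.snp_id: t for t in load_crc_verification_counts()}


@pytest.fixture(scope="session")
def crc_results(crc_tables):
    """Fitted verification report for the bundled seven-SNP dataset."""
    from poolgwas import VerificationStudy

    return VerificationStudy(list(crc_tables.values())).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
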