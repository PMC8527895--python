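import numpy as np
import pytest

from speechtrf.languages import make_toy_languages, sample_transcript
from speechtrf.pipeline import analyze_cohort, kernel_recovery
from speechtrf.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def lang():
    return make_toy_languages(seed=1)


@pytest.fixture(scope="session")
def transcript(lang):
    return sample_transcript(lang, 30.0, seed=2)


@pytest.fixture(scope="session")
def recovery_report():
    """Noiseless convolution-oracle recovery (10 trials x 60 s, 8 channels)."""
    return kernel_recovery(seed=1)


@pytest.fixture(scope="session")
def cohort_analysis():
    """Planted-effect cohort at 0 dB SNR: 8 subjects per group, full
    TRF/PDM/decoding hierarchy."""
    cohort = simulate_cohort(CohortConfig(n_per_group=8, snr_db=0.0, seed=1))
    return analyze_cohort(cohort, seed=1)


@pytest.fixture(scope="session")
def highsnr_analysis():
    """Same cohort design at high SNR (20 dB) for the near-noiseless
    classification checks."""
    cohort = simulate_cohort(CohortConfig(n_per_group=8, snr_db=20.0, seed=2))
    return analyze_cohort(cohort, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
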