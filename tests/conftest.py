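import numpy as np
import pytest

from runload import BoutSimParams, simulate_bout


@pytest.fixture(scope="session")
def clean_bout():
    """Zero-noise bout with fully programmed ground truth."""
    params = BoutSimParams(
        cadence_spm=160.0,
        pta_target_g=10.0,
        la_target=0.20,
        rsh_target=0.5,
        duration_s=60.0,
        seed=1,
    )
    return params, simulate_bout(params)


@pytest.fixture(scope="session")
def noisy_bout():
    params = BoutSimParams(
        cadence_spm=166.0,
        pta_target_g=10.6,
        la_target=0.08,
        rsh_target=0.41,
        duration_s=120.0,
        amp_cv=0.05,
        timing_jitter_cv=0.03,
        noise_sd_g=0.1,
        seed=42,
    )
    return params, simulate_bout(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
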