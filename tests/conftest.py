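import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "seqqc",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("seqqc")

from seqqc.synthetic_data import CohortConfig, PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-sized cohort (122 sessions, 19 tools) with planted poor sessions."""
    cfg = CohortConfig(seed=11)
    scans, session_iqm, labels = generate_cohort(cfg)
    return scans, session_iqm, labels


@pytest.fixture()
def noiseless_phantom():
    from seqqc.synthetic_data import generate_phantom

    spec = PhantomSpec(
        shape=(24, 24, 24), sd_air=0.0, sd_gm=0.0, sd_wm=0.0,
        smooth_fwhm_mm=0.0, bias_amplitude=0.0, seed=0,
    )
    return generate_phantom(spec), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
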