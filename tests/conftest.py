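import numpy as np
import pytest

from gaitkit.simulate import GaitProfile, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_recording():
    """Noise-free 6-cycle walk at 100 steps/min, 60% stance."""
    profile = GaitProfile(
        cadence_spm=100.0, stance_fraction=0.6, n_cycles=6,
        noise_sd=0.0, drift_sd=0.0, seed=1,
    )
    return generate_recording(profile)


@pytest.fixture
def noisy_recording():
    """Default-noise recording with a lead-in, as the cohort generator makes."""
    profile = GaitProfile(
        cadence_spm=104.0, stance_fraction=0.61, n_cycles=6,
        lead_in_s=0.3, seed=7,
    )
    return generate_recording(profile)
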