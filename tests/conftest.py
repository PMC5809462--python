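import numpy as np
import pytest

from toipulse import synthetic as syn


@pytest.fixture(scope="session")
def small_subject():
    """A 30 s, 32x32, 60 fps synthetic subject shared by fast tests."""
    cfg = syn.SyntheticConfig(seed=42, duration_s=30.0, frame_shape=(32, 32),
                              hr_bpm=72)
    return syn.generate_subject(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
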