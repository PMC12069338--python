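import numpy as np
import pytest

from msacnn.preprocess import WindowSpec
from msacnn.synth import SynthSpec, make_separable_windows


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small separable 3-class corpus at a low sampling rate (fast to train)."""
    spec = SynthSpec(n_classes=3, channels=6, fs=100.0, bout_s=5.0, rest_s=3.0,
                     reps=2, snr_db=20.0, seed=5, band=(10.0, 45.0))
    return make_separable_windows(spec, WindowSpec(window_ms=256.0, step_ms=100.0))
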