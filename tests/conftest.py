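import numpy as np
import pytest

import swallowflow as sf

#: reduced sampling rate used throughout the tests; all features are defined
#: relative to the sampling rate, so the pipeline is rate-agnostic
FS = 500.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def profiles():
    return sf.make_default_profiles()


@pytest.fixture(scope="session")
def small_session():
    """One participant's full synthetic session at the reduced rate."""
    cfg = sf.SyntheticConfig(n_participants=1, sampling_rate=FS, seed=7,
                             lead_in_s=2.0)
    recordings, baseline = sf.generate_session(cfg, 0)
    return cfg, recordings, baseline
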