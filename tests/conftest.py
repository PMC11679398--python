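import numpy as np
import pytest

from ecgfusion.synth_ecg import SynthRecordConfig, generate_record


@pytest.fixture(scope="session")
def noiseless_record():
    """20-beat record with no noise/wander: ground truth is exact."""
    cfg = SynthRecordConfig(n_beats=20, noise_sd=0.0,
                            baseline_wander_amp=0.0, seed=11)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def noisy_record():
    """100-beat record at the default noise conditions."""
    cfg = SynthRecordConfig(n_beats=100, seed=7)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
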