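import numpy as np
import pytest

from cardiophys.synth import ECGGenParams, APGenParams, generate_ecg, \
    generate_ap_train


@pytest.fixture(scope="session")
def wt_ecg():
    """A clean wild-type-like ECG with its ground truth (session-cached)."""
    params = ECGGenParams(seed=101, noise_sd=0.01)
    signal, truth = generate_ecg(params)
    return params, signal, truth


@pytest.fixture(scope="session")
def wt_ap_train():
    """A wild-type-like AP train with its ground truth (session-cached)."""
    params = APGenParams(seed=202, noise_sd=0.5, beat_to_beat_sd=5.0)
    signal, truth, protocol, stim = generate_ap_train(params)
    return params, signal, truth, protocol, stim


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
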