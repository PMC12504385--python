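import numpy as np
import pytest

from mbcatt import ModelConfig, SynthConfig, build_window_set, generate_subject


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """A scaled-down architecture for fast structural/gradient tests; keeps
    every method-fixed kernel and the 4-head attention."""
    return ModelConfig(
        n_classes=2, n_eeg_ch=12, eeg_samples=40, n_fnirs_ch=12,
        fnirs_samples=20, eeg_filters=(2, 2, 2, 2, 3, 3),
        fnirs_filters=(2, 2, 3, 3),
        eeg_pools=((2, 1), (2, 1), (1, 1), (1, 1), (1, 1), (1, 1)),
        fnirs_pools=((2, 1), (1, 1), (1, 1), (1, 1)),
        fc_widths=(8, 8), d_model=8, tokens=2, dropout=0.0)


@pytest.fixture()
def tiny_batch(tiny_config):
    rng = np.random.default_rng(42)
    eeg = rng.standard_normal((4, tiny_config.n_eeg_ch,
                               tiny_config.eeg_samples)).astype(np.float32)
    fnirs = rng.standard_normal((4, tiny_config.n_fnirs_ch,
                                 tiny_config.fnirs_samples)).astype(np.float32)
    labels = np.array([0, 1, 0, 1])
    return eeg, fnirs, labels


@pytest.fixture(scope="session")
def nback_recording():
    """One deterministic synthetic n-back recording (2 trials per class)."""
    return generate_subject(SynthConfig(paradigm="nback", trials_per_class=2,
                                        seed=7), 0)


@pytest.fixture(scope="session")
def wg_recording():
    return generate_subject(SynthConfig(paradigm="wg", trials_per_class=2,
                                        seed=7), 0)


@pytest.fixture(scope="session")
def nback_windows(nback_recording):
    return build_window_set(nback_recording)


@pytest.fixture(scope="session")
def wg_windows(wg_recording):
    return build_window_set(wg_recording)
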