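import numpy as np
import pytest

import hybridmp as h


@pytest.fixture(scope="session")
def small_runs():
    """Three short runs at moderate SNR (8 movements each)."""
    paradigm = h.ParadigmConfig(n_movements=8)
    templates = h.TemplateConfig(noise_sd=2.0)
    return h.generate_runs(3, paradigm, templates, n_eeg_channels=8,
                           n_emg_channels=4, seed=42)


@pytest.fixture(scope="session")
def small_config():
    """Reduced EMG grid keeps the training search fast in unit tests."""
    grid = h.EMGGrid(w_vf_ms=(20, 50), w_at_ms=(1000, 2000), p=(4, 8))
    return h.SessionConfig(seed=0, emg_grid=grid)


@pytest.fixture(scope="session")
def small_result(small_runs, small_config):
    """Trained + evaluated session shared across integration tests."""
    return h.run_session(small_runs[:2], small_runs[2], small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
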