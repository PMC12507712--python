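import warnings

import numpy as np
import pytest

import mne

mne.set_log_level("ERROR")
warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning, module="mne")

from mi_erd import (  # noqa: E402
    SimulationConfig,
    generate_recording,
    PreprocessParams,
    preprocess_continuous,
    epoch_and_reject,
)


@pytest.fixture(scope="session")
def default_subject():
    """One synthetic subject under the default study conditions."""
    rec, truth = generate_recording(SimulationConfig(seed=1))
    return rec, truth


@pytest.fixture(scope="session")
def clean_epochs(default_subject):
    """Fully preprocessed and epoched default subject (shared, read-only)."""
    rec, _ = default_subject
    params = PreprocessParams()
    clean, report = preprocess_continuous(rec, params)
    epochs = epoch_and_reject(clean, params)
    epochs.meta["preprocess_report"] = report
    return epochs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
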