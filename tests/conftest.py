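import numpy as np
import pytest

from eeglike import screening, spectra, syndata


@pytest.fixture(scope="session")
def small_recording():
    """A small planted-pattern recording: 4 channels (E1/E2 carry the burst),
    10 s trials, 96 trials total."""
    cfg = syndata.SimConfig(
        n_subjects=8, n_paintings=12, n_channels=4,
        trial_seconds=10.0, blank_seconds=5.0, seed=20_240_101,
    )
    return cfg, syndata.simulate_recording(cfg)


@pytest.fixture(scope="session")
def small_spectrograms(small_recording):
    _, rec = small_recording
    return [
        spectra.band_power(spectra.resample_to_104(s))
        for s in spectra.slice_trials(rec)
    ]


@pytest.fixture(scope="session")
def small_labels(small_recording):
    _, rec = small_recording
    return screening.bin_scores(rec.scores, screening.BINNING_RULES["D34"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
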