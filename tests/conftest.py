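import numpy as np
import pytest

from neurovisceral import synth


@pytest.fixture(scope="session")
def modulated_rr():
    """A 5-minute R-R series with LF+HF modulation and its beat times."""
    spec = synth.RRGenSpec(
        mean_rr=850, lf_amp=30, hf_amp=30, noise_sd=10, duration_s=300, seed=3
    )
    return synth.generate_rr_series(spec)


@pytest.fixture(scope="session")
def shared_source_eeg():
    """Two channels sharing a theta-band source with unit weights and unit
    noise: analytic in-band magnitude-squared coherence 0.25."""
    spec = synth.EEGGenSpec(
        n_channels=2,
        fs=250,
        duration_s=120,
        band_sources=((4.0, 8.0, (1.0, 1.0)),),
        channel_noise_sd=1.0,
        seed=0,
    )
    return synth.generate_eeg(spec), spec
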