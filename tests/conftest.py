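import numpy as np
import pytest

from eegworkload import pipeline, synthetic


@pytest.fixture(scope="session")
def short_session():
    """One simulated subject with 60-s circuit segments (default effects)."""
    spec = synthetic.SimulationSpec(iaf_hz=10.5, seed=42)
    protocol = synthetic.default_protocol(segment_duration_s=60.0)
    rec, truth = synthetic.simulate_session(spec, protocol)
    return spec, protocol, rec, truth


@pytest.fixture(scope="session")
def trained_session(short_session):
    """Model + spectra trained on the short session's calibration segments."""
    _, _, rec, _ = short_session
    model, spectra = pipeline.train_session(rec, rec.annotations)
    return model, spectra


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
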