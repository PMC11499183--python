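import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

from qtaudit.synth import RhythmSpec, SynthConfig, synthesize_record


@pytest.fixture(scope="session")
def clean_sinus():
    """Noise-free sinus record at HR 60, true QT 400 ms, with truth."""
    cfg = SynthConfig(
        seed=11, noise_sd_mv=0.0, baseline_wander_amp_mv=0.0,
        rhythm=RhythmSpec(mean_rr_ms=1000.0, rr_cv=0.0),
    )
    return synthesize_record(cfg, record_id="clean")


@pytest.fixture
def make_record():
    """Factory for synthetic records with keyword overrides."""

    def _make(record_id="rec", **kw):
        kw.setdefault("seed", 0)
        return synthesize_record(SynthConfig(**kw), record_id=record_id)

    return _make


@pytest.fixture
def gaussian_t():
    """Factory for an isolated gaussian T wave sampled at fs."""

    def _make(center_ms=600.0, sigma_ms=40.0, amplitude_mv=0.35, fs=500.0,
              duration_ms=2000.0, baseline_mv=0.0, noise_sd=0.0, seed=0):
        t = np.arange(int(duration_ms * fs / 1000.0)) * (1000.0 / fs)
        x = baseline_mv + amplitude_mv * np.exp(
            -0.5 * ((t - center_ms) / sigma_ms) ** 2)
        if noise_sd:
            x = x + np.random.default_rng(seed).normal(0, noise_sd, x.size)
        return x

    return _make
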