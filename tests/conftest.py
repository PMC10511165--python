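import numpy as np
import pytest

from stvqt import SynthConfig, synthesize_record


def clean_config(**kw) -> SynthConfig:
    """Single-lead, noise-free generation for measurement-accuracy tests."""
    base = dict(fs=1000.0, duration=50.0, leads=("II",), seed=0,
                noise_wander=(0.0, 0.3), noise_broadband=0.0,
                noise_powerline=0.0)
    base.update(kw)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def clean_record():
    """One noise-free 62-beat record with constant prescribed QT."""
    cfg = clean_config(qt_white_sd=0.0)
    return synthesize_record(cfg)


@pytest.fixture(scope="session")
def default_noise_record():
    """A record under the default (realistic) noise conditions."""
    cfg = SynthConfig(duration=50.0, leads=("II",), seed=7, stv_target=1.5)
    return synthesize_record(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
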