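import numpy as np
import pytest

from szdetect.io import NONSEIZURE, SEIZURE, AnnotationSet, Interval, Recording
from szdetect.pipeline import run_e2e


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """4-channel, 1000-sample recording tiled by nonseizure/seizure/nonseizure."""
    data = rng.standard_normal((4, 1000))
    data[:, 400:600] += 8.0 * np.sin(np.linspace(0, 40, 200))  # embedded event
    rec = Recording(data=data, fs_hz=1000.0, source_id="fixture")
    ann = AnnotationSet(
        intervals=[
            Interval(0, 400, NONSEIZURE),
            Interval(400, 600, SEIZURE),
            Interval(600, 1000, NONSEIZURE),
        ],
        recording_id="fixture",
    )
    return rec, ann


@pytest.fixture(scope="session")
def e2e_result():
    """Full-scale synthetic recovery run, shared by the acceptance tests.

    16 channels, 20 kHz, 60 s, 20 embedded burst events at snr 6; ~20 000
    windows from all three augmentation strategies; tiny model preset.
    """
    return run_e2e(seed=0)
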