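"""Shared fixtures and helpers for the hydramea test suite.

Most fixtures run at a reduced sampling rate (1 kHz instead of the device's
10 kHz) with the detection windows rescaled to the same physical durations,
so the suite stays fast while exercising identical time-domain behavior.
"""

import numpy as np
import pytest

from hydramea.detection import DetectionParams, detect_peaks
from hydramea.io import RecordingSet, select_best_channel
from hydramea.preprocessing import preprocess
from hydramea.simulate import SynthConfig


def fast_params(sample_rate: float = 1000.0, **overrides) -> DetectionParams:
    """Detection parameters with windows rescaled to a given sampling rate.

    Keeps the default physical values: 20 ms averaging window, 20 ms
    derivative step.
    """
    defaults = dict(
        normalized_threshold=0.3,
        average_window=max(int(round(0.02 * sample_rate)), 1),
        time_threshold=0.02,
        refractory_period=1.0,
        cp_threshold=10.0,
        icbi_threshold=10.0,
    )
    defaults.update(overrides)
    return DetectionParams(**defaults)


def fast_config(**overrides) -> SynthConfig:
    """A small, quick-to-render simulation scenario (1 kHz, one channel)."""
    defaults = dict(
        duration_s=120.0,
        sample_rate_hz=1000.0,
        n_channels=1,
        burst_rate=2.0,
        intra_burst_interval=(1.5, 0.25),
        peaks_per_burst=4.0,
        noise_sigma=0.125,
        min_gap_s=12.0,
        seed=0,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


def run_detection(rec: RecordingSet, params: DetectionParams, channel: int | None = None):
    """Select a channel (best SNR unless given), preprocess and detect."""
    ch = select_best_channel(rec) if channel is None else channel
    smoothed = preprocess(rec.traces[ch], params.average_window)
    return detect_peaks(smoothed, params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
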