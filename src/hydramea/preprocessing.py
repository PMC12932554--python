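"""Amplitude normalization and moving-average smoothing of one channel.

The detection stage is amplitude-agnostic: the selected trace is first
rescaled by its largest absolute excursion so that thresholds are expressed
as fractions of the recording's own dynamic range, then smoothed with a
centered moving average (default 200 samples, i.e. 20 ms at 10 kHz) to
suppress high-frequency noise while leaving the slow contraction-pulse
waveform intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ParameterError
from .io import RecordingTrace

__all__ = ["SmoothedTrace", "normalize", "smooth", "preprocess"]

#: default moving-average window, samples (20 ms at 10 kHz)
DEFAULT_AVERAGE_WINDOW = 200


@dataclass
class SmoothedTrace:
    """Normalized and smoothed single-channel signal on its time base."""

    times: np.ndarray
    signal_norm: np.ndarray
    signal_mean: np.ndarray
    average_window: int
    source_id: str = ""

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


def normalize(samples: np.ndarray | RecordingTrace) -> np.ndarray:
    """Divide by the maximum absolute value; output peak magnitude is 1.

    Extracellular deflections can be negative-going, so the divisor is the
    absolute maximum rather than the signed maximum — a signed divisor would
    flip the polarity of negative-dominant traces.
    """
    x = samples.samples if isinstance(samples, RecordingTrace) else samples
    x = np.asarray(x, dtype=float)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak == 0.0:
        raise DegenerateInputError("cannot normalize an identically zero trace")
    return x / peak


def smooth(signal: np.ndarray, average_window: int) -> np.ndarray:
    """Centered moving average of length ``average_window``.

    Edges use the truncated window (mean over the samples actually
    available), so no phantom values are introduced and the output has the
    same length as the input.
    """
    x = np.asarray(signal, dtype=float)
    if not 1 <= average_window <= x.size:
        raise ParameterError(
            f"average_window must be in [1, {x.size}], got {average_window}"
        )
    return (
        pd.Series(x)
        .rolling(average_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def preprocess(
    trace: RecordingTrace, average_window: int = DEFAULT_AVERAGE_WINDOW
) -> SmoothedTrace:
    """Normalize then smooth one channel, keeping its time base."""
    norm = normalize(trace)
    return SmoothedTrace(
        times=trace.times,
        signal_norm=norm,
        signal_mean=smooth(norm, average_window),
        average_window=average_window,
        source_id=trace.source_id,
    )
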