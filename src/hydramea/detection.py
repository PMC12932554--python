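"""Contraction-pulse peak detection by successive centered finite differences.

The detector scans the smoothed, normalized trace left to right and accepts
a sample as a peak only when three conditions hold simultaneously:

1. the smoothed signal exceeds the *normalized threshold*;
2. the first derivative is positive (a rising edge);
3. the second derivative has just changed sign from positive to negative
   within the half-stencil preceding the sample (the concave-down onset
   that marks an approaching apex).

Both derivatives use a centered finite difference over a time window
``theta`` (the *time threshold*); the second derivative is the composition
of two first-difference stencils applied to the first-derivative values —
deliberately not the direct three-point second difference, which trades a
little noise sensitivity for sharper discrimination of curvature changes.
After an acceptance the scan pointer jumps past a fixed *refractory period*
so overlapping or redundant detections of the same pulse are impossible.

Detected peak times are the accepted sample's own timestamp; no sub-sample
interpolation is attempted.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .preprocessing import DEFAULT_AVERAGE_WINDOW, SmoothedTrace

__all__ = [
    "DetectionParams",
    "PeakTrain",
    "first_derivative",
    "second_derivative",
    "detect_peaks",
    "write_peaks",
    "read_peaks",
]


@dataclass
class DetectionParams:
    """All tunable thresholds of the detection and classification pipeline.

    Parameters
    ----------
    normalized_threshold : float
        Fraction of the recording's peak amplitude the smoothed signal must
        exceed, in (0, 1).
    average_window : int
        Moving-average window, samples.
    time_threshold : float
        Derivative step ``theta`` in seconds; must span an even number of
        sample intervals so the half-step lands on the sample grid.
    refractory_period : float
        Dead time after an accepted peak, seconds.
    cp_threshold, icbi_threshold : float
        Inter-peak-interval boundaries (seconds) separating contraction
        pulses (< cp_threshold) from inter-contraction-burst intervals
        (>= icbi_threshold). Equal by default so the split is exhaustive.
    count_convention : str
        'intervals' counts a burst's CPs as its CP-classified intervals;
        'peaks' counts the peaks spanning them (one more per burst).
    """

    normalized_threshold: float = 0.3
    average_window: int = DEFAULT_AVERAGE_WINDOW
    time_threshold: float = 0.02
    refractory_period: float = 1.0
    cp_threshold: float = 10.0
    icbi_threshold: float = 10.0
    count_convention: str = "intervals"

    def __post_init__(self) -> None:
        if not 0.0 < self.normalized_threshold < 1.0:
            raise ParameterError("normalized_threshold must be in (0, 1)")
        if self.time_threshold <= 0:
            raise ParameterError("time_threshold must be positive")
        if self.refractory_period < 0:
            raise ParameterError("refractory_period must be non-negative")
        if self.cp_threshold > self.icbi_threshold:
            raise ParameterError("cp_threshold must not exceed icbi_threshold")
        if self.average_window < 1:
            raise ParameterError("average_window must be >= 1")
        if self.count_convention not in ("intervals", "peaks"):
            raise ParameterError("count_convention must be 'intervals' or 'peaks'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        return cls(**d)


@dataclass
class PeakTrain:
    """Ordered detected (or planted) peak times for one recording."""

    source_id: str
    peak_times: np.ndarray
    final_time: float
    params: DetectionParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size and np.any(np.diff(self.peak_times) <= 0):
            raise ParameterError("peak_times must be strictly increasing")
        if self.peak_times.size and (
            self.peak_times[0] < 0 or self.peak_times[-1] > self.final_time + 1e-12
        ):
            raise ParameterError("peak_times must lie within [0, final_time]")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)


def _half_step_samples(times: np.ndarray, theta: float) -> int:
    """theta/2 expressed in sample intervals; must land on the grid."""
    dt = float(times[1] - times[0])
    m = theta / (2.0 * dt)
    m_int = int(round(m))
    if m_int < 1 or abs(m - m_int) > 1e-6 * max(1.0, m):
        raise ParameterError(
            f"time_threshold {theta} s must span an even number (>= 2) of "
            f"sample intervals (dt = {dt} s)"
        )
    return m_int


def first_derivative(
    signal: np.ndarray, times: np.ndarray, theta: float
) -> np.ndarray:
    """Centered finite difference f'(t) = [x(t+theta/2) - x(t-theta/2)] / theta.

    Boundary points where the stencil exits the record are NaN. Exact for
    affine signals; O(theta^2) error otherwise.
    """
    x = np.asarray(signal, dtype=float)
    m = _half_step_samples(times, theta)
    n = x.size
    if n <= 2 * m:
        raise ParameterError("record shorter than the derivative stencil")
    out = np.full(n, np.nan)
    out[m : n - m] = (x[2 * m :] - x[: n - 2 * m]) / theta
    return out


def second_derivative(
    first_deriv: np.ndarray, times: np.ndarray, theta: float
) -> np.ndarray:
    """Centered finite difference of already-computed first-derivative values.

    Composing two first-order stencils (rather than the direct three-point
    second difference) is exact for quadratics and emphasizes curvature
    transitions.
    """
    return first_derivative(first_deriv, times, theta)


def detect_peaks(
    smoothed: SmoothedTrace, params: DetectionParams, source_id: str | None = None
) -> PeakTrain:
    """Scan the smoothed trace and return all accepted contraction-pulse peaks.

    See the module docstring for the three acceptance conditions and the
    refractory skip. Raises :class:`ParameterError` when the record is too
    short for the derivative stencil at ``params.time_threshold``.
    """
    x = smoothed.signal_mean
    t = smoothed.times
    m = _half_step_samples(t, params.time_threshold)
    n = x.size
    if n <= 4 * m:
        raise ParameterError(
            "record too short for the composed second-derivative stencil"
        )
    f1 = first_derivative(x, t, params.time_threshold)
    f2 = second_derivative(f1, t, params.time_threshold)

    # concavity transition: f'' goes + -> <=0 between consecutive samples
    with np.errstate(invalid="ignore"):
        cross = (f2[:-1] > 0) & (f2[1:] <= 0)
    # condition holds at i when a crossing occurred in [i-m, i-1]
    csum = np.concatenate(([0], np.cumsum(cross)))
    idx = np.arange(n)
    lo = np.maximum(idx - m, 0)
    hi = np.minimum(idx, cross.size)
    recent_cross = (csum[hi] - csum[lo]) > 0

    with np.errstate(invalid="ignore"):
        ok = (x > params.normalized_threshold) & (f1 > 0) & recent_cross

    candidates = np.flatnonzero(ok)
    cand_times = t[candidates]
    peaks: list[float] = []
    j = 0
    while j < candidates.size:
        tj = cand_times[j]
        peaks.append(float(tj))
        # skip ahead past the refractory period
        j = int(np.searchsorted(cand_times, tj + params.refractory_period, "left"))
    duration = t[-1] - t[0] + (t[1] - t[0])
    return PeakTrain(
        source_id=source_id if source_id is not None else smoothed.source_id,
        peak_times=np.asarray(peaks) - t[0],
        final_time=float(duration),
        params=params,
    )


def write_peaks(train: PeakTrain, path: str | os.PathLike) -> None:
    """Serialize a peak train as CSV plus a JSON sidecar with its parameters."""
    pd.DataFrame(
        {
            "source_id": train.source_id,
            "peak_index": np.arange(train.n_peaks),
            "time_s": train.peak_times,
        }
    ).to_csv(path, index=False)
    sidecar = {"source_id": train.source_id, "final_time_s": train.final_time}
    if train.params is not None:
        sidecar["params"] = train.params.to_dict()
    with open(f"{os.fspath(path)}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_peaks(path: str | os.PathLike) -> PeakTrain:
    """Load a peak train written by :func:`write_peaks`."""
    df = pd.read_csv(path)
    with open(f"{os.fspath(path)}.json") as fh:
        sidecar = json.load(fh)
    params = (
        DetectionParams.from_dict(sidecar["params"]) if "params" in sidecar else None
    )
    return PeakTrain(
        source_id=str(sidecar["source_id"]),
        peak_times=df["time_s"].to_numpy(dtype=float),
        final_time=float(sidecar["final_time_s"]),
        params=params,
    )
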