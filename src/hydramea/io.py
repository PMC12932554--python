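"""Reading, writing and channel selection for multi-channel MEA recordings.

Two on-disk dialects are supported:

* **HDF5 (native)** — root attributes ``sample_rate_hz`` (float) and
  ``n_channels`` (int); dataset ``/recording/channel_data`` shaped
  ``(n_channels, n_samples)``, float32; optional ``/recording/time_s``;
  optional ``/ground_truth/peak_times_s`` written by the simulator.
  A best-effort fallback reader also accepts the vendor-style nested path
  ``/Data/Recording_0/AnalogStream/Stream_0/ChannelData``.
* **CSV** — header row required; first column is time in seconds, remaining
  columns are channels (``time,ch0,ch1,...``).

Channel indexing is 0-based everywhere.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import h5py
import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, FormatError, IntegrityError

__all__ = [
    "RecordingTrace",
    "RecordingSet",
    "read_recording",
    "write_recording",
    "select_best_channel",
    "snr_score",
]

#: vendor-style fallback dataset path attempted on HDF5 read
VENDOR_CHANNEL_DATA = "/Data/Recording_0/AnalogStream/Stream_0/ChannelData"
NATIVE_CHANNEL_DATA = "/recording/channel_data"


@dataclass
class RecordingTrace:
    """One channel's uniformly sampled voltage series.

    Sample ``k`` is located at time ``t0 + k / sample_rate`` seconds.
    Amplitudes are device-native arbitrary units.
    """

    channel_id: int
    sample_rate: float
    samples: np.ndarray
    t0: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise IntegrityError("sample_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise IntegrityError("a trace needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / sample_rate)."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


@dataclass
class RecordingSet:
    """All channels of one registration; traces share rate and length."""

    traces: list[RecordingTrace]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.traces:
            raise IntegrityError("RecordingSet requires at least one trace")
        sr = {t.sample_rate for t in self.traces}
        if len(sr) != 1:
            raise IntegrityError(f"traces disagree on sample_rate: {sorted(sr)}")
        lengths = {t.n_samples for t in self.traces}
        if len(lengths) != 1:
            raise IntegrityError(f"ragged channel lengths: {sorted(lengths)}")

    @property
    def n_channels(self) -> int:
        return len(self.traces)

    @property
    def sample_rate(self) -> float:
        return self.traces[0].sample_rate

    @property
    def n_samples(self) -> int:
        return self.traces[0].n_samples

    @property
    def source_id(self) -> str:
        return self.traces[0].source_id

    def to_array(self) -> np.ndarray:
        """Stack channels into a (n_channels, n_samples) array."""
        return np.stack([t.samples for t in self.traces])


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("hdf5", "csv"):
            raise FormatError(f"unknown format {fmt!r}; expected 'hdf5' or 'csv'")
        return fmt
    ext = os.path.splitext(os.fspath(path))[1].lower()
    return "csv" if ext == ".csv" else "hdf5"


def write_recording(
    rec: RecordingSet,
    path: str | os.PathLike,
    fmt: str | None = None,
    ground_truth_peak_times: Sequence[float] | None = None,
) -> None:
    """Write a :class:`RecordingSet` in the native HDF5 dialect or as CSV.

    HDF5 stores samples as float32 (the device's native depth); reading back
    reproduces the stored float32 values bit-exactly. ``ground_truth_peak_times``
    (HDF5 only) records simulator-planted event times for later scoring.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["sample_rate_hz"] = float(rec.sample_rate)
            f.attrs["n_channels"] = int(rec.n_channels)
            if rec.source_id:
                f.attrs["source_id"] = rec.source_id
            grp = f.create_group("recording")
            # track_times=False keeps files byte-identical across runs
            grp.create_dataset(
                "channel_data",
                data=rec.to_array().astype(np.float32),
                track_times=False,
            )
            if ground_truth_peak_times is not None:
                gt = f.create_group("ground_truth")
                gt.create_dataset(
                    "peak_times_s",
                    data=np.asarray(ground_truth_peak_times, dtype=float),
                    track_times=False,
                )
    else:
        t = rec.traces[0].times
        cols = {"time": t}
        for tr in rec.traces:
            cols[f"ch{tr.channel_id}"] = tr.samples
        pd.DataFrame(cols).to_csv(path, index=False)


def _read_hdf5(path: str | os.PathLike) -> RecordingSet:
    source_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    with h5py.File(path, "r") as f:
        if NATIVE_CHANNEL_DATA in f:
            data = np.asarray(f[NATIVE_CHANNEL_DATA])
            sr = float(f.attrs["sample_rate_hz"])
        elif VENDOR_CHANNEL_DATA in f:
            data = np.asarray(f[VENDOR_CHANNEL_DATA])
            if "sample_rate_hz" in f.attrs:
                sr = float(f.attrs["sample_rate_hz"])
            else:
                raise FormatError(
                    "vendor-style file found but sampling rate is not stored "
                    "where this reader can find it; add a root attribute "
                    "'sample_rate_hz' or convert to the native dialect"
                )
        else:
            raise FormatError(
                f"no channel data found: expected dataset {NATIVE_CHANNEL_DATA} "
                f"(or vendor-style {VENDOR_CHANNEL_DATA})"
            )
        metadata = {k: v for k, v in f.attrs.items()}
        gt_times = None
        if "ground_truth/peak_times_s" in f:
            gt_times = np.asarray(f["ground_truth/peak_times_s"])
    if data.ndim != 2:
        raise IntegrityError(f"channel data must be 2-D, got shape {data.shape}")
    metadata["source_id"] = source_id
    if gt_times is not None:
        metadata["ground_truth_peak_times_s"] = gt_times
    traces = [
        RecordingTrace(channel_id=i, sample_rate=sr, samples=row, source_id=source_id)
        for i, row in enumerate(data)
    ]
    return RecordingSet(traces=traces, metadata=metadata)


def _read_csv(path: str | os.PathLike) -> RecordingSet:
    source_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0].strip().lower() != "time":
        raise FormatError(
            "CSV must have a header with first column 'time' (seconds) "
            "followed by one column per channel"
        )
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise IntegrityError("CSV needs at least 2 rows of samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12) or dt[0] <= 0:
        raise IntegrityError("CSV time column must be uniformly increasing")
    sr = 1.0 / dt[0]
    traces = [
        RecordingTrace(
            channel_id=i,
            sample_rate=sr,
            samples=df.iloc[:, i + 1].to_numpy(dtype=float),
            t0=float(t[0]),
            source_id=source_id,
        )
        for i in range(df.shape[1] - 1)
    ]
    return RecordingSet(traces=traces, metadata={"source_id": source_id})


def read_recording(path: str | os.PathLike, fmt: str | None = None) -> RecordingSet:
    """Read a recording; format inferred from the extension unless given.

    Returns all channels in file order. Simulator ground-truth peak times,
    when present in an HDF5 file, appear in ``metadata['ground_truth_peak_times_s']``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such recording file: {path}")
    fmt = _infer_format(path, fmt)
    return _read_hdf5(path) if fmt == "hdf5" else _read_csv(path)


def snr_score(samples: np.ndarray, snr_window: int = 200) -> float:
    """Peak-to-peak amplitude of the smoothed trace over a robust noise scale.

    The noise scale is the median absolute deviation of the first difference,
    scaled to standard-deviation units (x1.4826) and divided by sqrt(2)
    because differencing doubles the variance of white noise. Needs no prior
    event detection, so it can rank channels before any analysis.
    """
    from .preprocessing import smooth

    x = np.asarray(samples, dtype=float)
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    noise = 1.4826 * mad / np.sqrt(2.0)
    w = min(snr_window, x.size)
    signal = float(np.ptp(smooth(x, w)))
    if noise == 0.0:
        return np.inf if signal > 0 else np.nan
    return signal / noise


def select_best_channel(
    rec: RecordingSet,
    snr_window: int = 200,
    scorer: Callable[[np.ndarray], float] | None = None,
) -> int:
    """Index of the channel with the highest signal-to-noise ratio.

    Ties break toward the lowest index. ``scorer`` may replace the default
    :func:`snr_score` statistic. Raises :class:`DegenerateInputError` when
    every channel is constant (no noise estimate, no signal).
    """
    if scorer is None:
        scores = np.array([snr_score(t.samples, snr_window) for t in rec.traces])
    else:
        scores = np.array([scorer(t.samples) for t in rec.traces])
    if np.all(np.isnan(scores)):
        raise DegenerateInputError("all channels are constant; SNR undefined")
    return int(np.nanargmax(scores))
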