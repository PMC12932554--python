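"""Alignment, interval classification, burst segmentation and activity metrics.

After detection each recording is realigned so its first peak sits at time
zero (the pre-peak interval is discarded), and all recordings of a set are
truncated to the common comparison window ``t_last`` — the minimum realigned
recording length across the set. Inter-peak intervals, plus the terminal
interval from the last peak to ``t_last``, then tile ``[0, t_last]`` exactly
and are classified by duration:

* ``CP``   — interval shorter than the CP threshold: a contraction pulse
  inside a burst;
* ``IcBI`` — interval at or above the IcBI threshold: an inter-contraction
  burst interval (elongation / quiescence);
* ``ambiguous`` — only possible when the two thresholds differ; excluded
  from CTime/ETime with a warning.

Bursts are maximal runs of consecutive CP intervals. Summary metrics:
CTime = sum of CP durations, ETime = sum of IcBI durations, and the activity
index HyAI = CTime / ETime — the balance between contractile and elongation
behavior. When ETime is zero HyAI is flagged undefined rather than raising.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detection import DetectionParams, PeakTrain
from .exceptions import HydrameaError

__all__ = [
    "AlignedTrainSet",
    "EventTable",
    "ActivityMetrics",
    "align_and_window",
    "classify_intervals",
    "compute_metrics",
    "raster",
    "raster_plot",
    "write_events",
    "metrics_to_json",
    "metrics_from_json",
]

EVENT_COLUMNS = [
    "source_id",
    "event_index",
    "t_start_s",
    "t_end_s",
    "duration_s",
    "class",
    "burst_index",
]


@dataclass
class AlignedTrainSet:
    """Peak trains realigned to their first event and a common window."""

    trains: list[PeakTrain]
    t_last: float
    dropped_prefix: list[float]
    dropped_peaks: list[int]


@dataclass
class EventTable:
    """Classified inter-peak intervals tiling [0, t_last] for one recording.

    ``df`` columns: t_start_s, t_end_s, duration_s, class in
    {CP, IcBI, ambiguous}, burst_index (nullable integer).
    """

    source_id: str
    t_last: float
    df: pd.DataFrame
    params: DetectionParams = field(repr=False, default=None)


@dataclass
class ActivityMetrics:
    """Per-recording activity summary."""

    source_id: str
    t_last: float
    cpi: np.ndarray          # CP-classified interval durations, s
    icbi: np.ndarray         # IcBI-classified interval durations, s
    burst_time: np.ndarray   # summed CP durations per burst, s
    n_cp_burst: np.ndarray   # CP count per burst (see count_convention)
    ctime: float
    etime: float
    n_burst: int
    n_icbi: int
    n_cp: int
    hyai: float              # CTime / ETime; inf when ETime == 0 and CTime > 0
    hyai_defined: bool
    cv: dict = field(default_factory=dict)

    def scalars(self) -> dict:
        """Scalar metrics for tidy cross-recording tables."""
        return {
            "source_id": self.source_id,
            "t_last": self.t_last,
            "ctime": self.ctime,
            "etime": self.etime,
            "n_burst": self.n_burst,
            "n_icbi": self.n_icbi,
            "n_cp": self.n_cp,
            "hyai": self.hyai,
            "hyai_defined": self.hyai_defined,
            "mean_cpi": float(np.mean(self.cpi)) if self.cpi.size else np.nan,
            "mean_icbi": float(np.mean(self.icbi)) if self.icbi.size else np.nan,
            "mean_burst_time": (
                float(np.mean(self.burst_time)) if self.burst_time.size else np.nan
            ),
        }


def align_and_window(trains: Iterable[PeakTrain]) -> AlignedTrainSet:
    """Realign every train so its first peak is at 0; window to the common end.

    ``t_last`` is the minimum realigned recording length across the set, and
    peaks beyond it are dropped (counts reported). Trains with no peaks are
    excluded with a warning; an entirely empty set is an error.
    """
    kept: list[PeakTrain] = []
    for tr in trains:
        if tr.n_peaks == 0:
            warnings.warn(
                f"train {tr.source_id!r} has no peaks and is excluded from alignment",
                stacklevel=2,
            )
            continue
        kept.append(tr)
    if not kept:
        raise HydrameaError("no trains with peaks to align")
    prefixes = [float(tr.peak_times[0]) for tr in kept]
    realigned = [tr.peak_times - tr.peak_times[0] for tr in kept]
    final_times = [tr.final_time - p for tr, p in zip(kept, prefixes)]
    t_last = float(min(final_times))
    out, dropped = [], []
    for tr, times in zip(kept, realigned):
        inside = times[times <= t_last + 1e-12]
        dropped.append(int(times.size - inside.size))
        out.append(
            PeakTrain(
                source_id=tr.source_id,
                peak_times=inside,
                final_time=t_last,
                params=tr.params,
            )
        )
    total_dropped = sum(dropped)
    if total_dropped:
        warnings.warn(
            f"windowing to t_last={t_last:.3f} s dropped {total_dropped} peaks",
            stacklevel=2,
        )
    return AlignedTrainSet(
        trains=out, t_last=t_last, dropped_prefix=prefixes, dropped_peaks=dropped
    )


def _classify_duration(d: float, params: DetectionParams) -> str:
    if d < params.cp_threshold:
        return "CP"
    if d >= params.icbi_threshold:
        return "IcBI"
    return "ambiguous"


def classify_intervals(
    train: PeakTrain, t_last: float | None = None, params: DetectionParams | None = None
) -> EventTable:
    """Classify consecutive inter-peak intervals plus the terminal interval.

    The train must be aligned (first peak at time 0). The terminal interval
    runs from the last peak to ``t_last`` (taken as a non-negative duration)
    and is classified by the same rule, so the intervals tile ``[0, t_last]``
    exactly. Burst indices label maximal runs of consecutive CP intervals.
    """
    if params is None:
        params = train.params if train.params is not None else DetectionParams()
    if t_last is None:
        t_last = train.final_time
    if train.n_peaks == 0:
        raise HydrameaError("cannot classify a train with no peaks")
    if abs(train.peak_times[0]) > 1e-9:
        raise HydrameaError(
            "train is not aligned: first peak must be at time 0 "
            "(run align_and_window first)"
        )
    bounds = np.concatenate([train.peak_times, [t_last]])
    starts, ends = bounds[:-1], bounds[1:]
    durations = ends - starts
    classes = [_classify_duration(float(d), params) for d in durations]
    if "ambiguous" in classes:
        warnings.warn(
            "intervals between cp_threshold and icbi_threshold are ambiguous "
            "and excluded from CTime/ETime",
            stacklevel=2,
        )
    burst_index: list[object] = []
    b = -1
    prev_cp = False
    for c in classes:
        if c == "CP":
            if not prev_cp:
                b += 1
            burst_index.append(b)
            prev_cp = True
        else:
            burst_index.append(pd.NA)
            prev_cp = False
    df = pd.DataFrame(
        {
            "source_id": train.source_id,
            "event_index": np.arange(durations.size),
            "t_start_s": starts,
            "t_end_s": ends,
            "duration_s": durations,
            "class": classes,
            "burst_index": pd.array(burst_index, dtype="Int64"),
        }
    )
    return EventTable(source_id=train.source_id, t_last=float(t_last), df=df, params=params)


def _cv(values: np.ndarray) -> float:
    """Coefficient of variation sigma/|mu| (sample sd); NaN when undefined."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return np.nan
    mu = v.mean()
    if mu == 0:
        return np.nan
    return float(v.std(ddof=1) / abs(mu))


def compute_metrics(table: EventTable) -> ActivityMetrics:
    """Summarize an event table into per-recording activity metrics."""
    df = table.df
    cp = df[df["class"] == "CP"]
    icbi = df[df["class"] == "IcBI"]
    cpi = cp["duration_s"].to_numpy()
    icbi_d = icbi["duration_s"].to_numpy()
    ctime = float(cpi.sum())
    etime = float(icbi_d.sum())
    if cp.empty:
        burst_time = np.array([])
        n_cp_burst = np.array([], dtype=int)
    else:
        grouped = cp.groupby("burst_index", observed=True)["duration_s"]
        burst_time = grouped.sum().to_numpy()
        n_cp_burst = grouped.count().to_numpy()
    convention = table.params.count_convention if table.params else "intervals"
    if convention == "peaks":
        n_cp_burst = n_cp_burst + 1
    n_cp = int(n_cp_burst.sum())
    hyai_defined = etime > 0
    if hyai_defined:
        hyai = ctime / etime
    else:
        hyai = np.inf if ctime > 0 else np.nan
    cv = {
        "cpi": _cv(cpi),
        "icbi": _cv(icbi_d),
        "burst_time": _cv(burst_time),
        "n_cp_burst": _cv(n_cp_burst),
    }
    return ActivityMetrics(
        source_id=table.source_id,
        t_last=table.t_last,
        cpi=cpi,
        icbi=icbi_d,
        burst_time=burst_time,
        n_cp_burst=n_cp_burst,
        ctime=ctime,
        etime=etime,
        n_burst=int(burst_time.size),
        n_icbi=int(icbi_d.size),
        n_cp=n_cp,
        hyai=hyai,
        hyai_defined=bool(hyai_defined),
        cv=cv,
    )


def raster(aligned: AlignedTrainSet) -> pd.DataFrame:
    """Long-format raster: one row per event, columns (source_id, row, time_s)."""
    frames = [
        pd.DataFrame(
            {"source_id": tr.source_id, "row": i, "time_s": tr.peak_times}
        )
        for i, tr in enumerate(aligned.trains)
    ]
    if not frames:
        return pd.DataFrame(columns=["source_id", "row", "time_s"])
    return pd.concat(frames, ignore_index=True)


def raster_plot(aligned: AlignedTrainSet, path: str | os.PathLike) -> None:
    """Save an event-raster figure (rows = recordings, marks = peak times)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 0.5 + 0.35 * len(aligned.trains)))
    for i, tr in enumerate(aligned.trains):
        ax.eventplot(tr.peak_times, lineoffsets=i, linelengths=0.8, colors="k")
    ax.set_xlim(0, aligned.t_last)
    ax.set_yticks(range(len(aligned.trains)))
    ax.set_yticklabels([tr.source_id for tr in aligned.trains], fontsize=7)
    ax.set_xlabel("time since first contraction pulse (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_events(table: EventTable, path: str | os.PathLike) -> None:
    """Write an event table as CSV with the documented column set."""
    table.df.to_csv(path, index=False, columns=EVENT_COLUMNS)


def metrics_from_json(d: dict) -> ActivityMetrics:
    """Rebuild an :class:`ActivityMetrics` from its JSON view."""
    hyai = d["hyai"]
    if hyai is None:
        hyai = np.inf if (d["hyai_defined"] is False and d["ctime"] > 0) else np.nan
    return ActivityMetrics(
        source_id=d["source_id"],
        t_last=d["t_last"],
        cpi=np.asarray(d["cpi_s"], dtype=float),
        icbi=np.asarray(d["icbi_s"], dtype=float),
        burst_time=np.asarray(d["burst_time_s"], dtype=float),
        n_cp_burst=np.asarray(d["n_cp_burst"], dtype=int),
        ctime=d["ctime"],
        etime=d["etime"],
        n_burst=d["n_burst"],
        n_icbi=d["n_icbi"],
        n_cp=d["n_cp"],
        hyai=hyai,
        hyai_defined=bool(d["hyai_defined"]),
        cv={k: (np.nan if v is None else v) for k, v in d.get("cv", {}).items()},
    )


def metrics_to_json(metrics: ActivityMetrics) -> dict:
    """JSON-serializable view of an :class:`ActivityMetrics`."""

    def _clean(x):
        if isinstance(x, float) and not np.isfinite(x):
            return None
        return x

    d = metrics.scalars()
    out = {k: _clean(v) for k, v in d.items()}
    out["cpi_s"] = metrics.cpi.tolist()
    out["icbi_s"] = metrics.icbi.tolist()
    out["burst_time_s"] = metrics.burst_time.tolist()
    out["n_cp_burst"] = metrics.n_cp_burst.tolist()
    out["cv"] = {k: _clean(v) for k, v in metrics.cv.items()}
    return out
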