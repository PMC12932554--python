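"""Synthetic MEA recordings of Hydra-like bioelectrical activity.

The generator emulates the phenomenology of whole-animal extracellular
recordings: high-amplitude contraction pulses (CPs) arriving in rhythmic
bursts separated by long quiescent gaps, optional low-amplitude rhythmic
potentials (RPs) between bursts, channel-synchronous event timing with
per-channel amplitude variation (the animal spans the whole electrode
grid), and additive white electrode noise.

Timing model — a renewal process: quiescent gaps between bursts are a
shifted exponential (a hard minimum keeps the burst/quiescence dichotomy
clean), the number of CPs per burst is 1 + Poisson, and intra-burst
intervals are gamma-distributed. A ``slowdown_factor`` multiplies every
sampled interval, mimicking anesthetic rate suppression. Each CP is
rendered as a biphasic template (difference of two Gaussians); RPs are
single low Gaussians. All channels share event times and differ only by a
multiplicative gain.

Ground truth (planted apex times, burst membership, and the activity
metrics they imply) is returned alongside the recording and embedded in
HDF5 output, so detection and metric recovery can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .detection import DetectionParams, PeakTrain
from .events import ActivityMetrics, classify_intervals, compute_metrics
from .exceptions import ParameterError
from .io import RecordingSet, RecordingTrace

__all__ = ["SynthConfig", "GroundTruth", "simulate", "match_times"]


@dataclass
class SynthConfig:
    """Scenario parameters for the synthetic recording generator.

    Defaults describe an awake animal at the device's native resolution:
    10 kHz sampling on 60 channels, about one contraction burst per minute
    of ~5 pulses spaced ~2 s apart, quiescent gaps of at least 12 s, CP
    amplitude 1 (normalized units) over noise sigma 0.15, plus faint RPs.
    """

    duration_s: float = 600.0
    sample_rate_hz: float = 10_000.0
    n_channels: int = 60
    burst_rate: float = 1.0                 # bursts per minute
    intra_burst_interval: tuple = (2.0, 0.25)  # (mean s, coefficient of variation)
    peaks_per_burst: float = 5.0            # mean; count is 1 + Poisson(mean - 1)
    cp_amplitude: float = 1.0
    cp_width_s: float = 0.03
    rp_amplitude: float = 0.15              # 0 disables rhythmic potentials
    rp_rate_hz: float = 0.2
    rp_width_s: float = 0.15
    noise_sigma: float = 0.15
    channel_gains: np.ndarray | None = None  # default: lognormal(0, 0.4) draw
    min_gap_s: float = 12.0                 # hard floor on inter-burst gaps
    slowdown_factor: float = 1.0            # multiplies every sampled interval
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0 or self.n_channels < 1:
            raise ParameterError("duration, sample rate and channel count must be positive")
        if not self.cp_amplitude > self.rp_amplitude >= 0:
            raise ParameterError("need cp_amplitude > rp_amplitude >= 0")
        if self.noise_sigma < 0 or self.burst_rate < 0 or self.rp_rate_hz < 0:
            raise ParameterError("noise_sigma and rates must be non-negative")
        if self.peaks_per_burst < 1:
            raise ParameterError("peaks_per_burst mean must be >= 1")
        if self.slowdown_factor < 1:
            raise ParameterError("slowdown_factor must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["intra_burst_interval"] = list(self.intra_burst_interval)
        if d["channel_gains"] is not None:
            d["channel_gains"] = np.asarray(d["channel_gains"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "intra_burst_interval" in d:
            d["intra_burst_interval"] = tuple(d["intra_burst_interval"])
        if d.get("channel_gains") is not None:
            d["channel_gains"] = np.asarray(d["channel_gains"], dtype=float)
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted event times and the metrics they imply under given thresholds."""

    cp_times_s: np.ndarray
    burst_membership: np.ndarray
    rp_times_s: np.ndarray
    true_metrics: ActivityMetrics | None = field(default=None, repr=False)


def match_times(
    detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.025
) -> tuple[int, float, float]:
    """Greedy one-to-one matching of detected to planted event times.

    Both inputs must be sorted. Returns (n_matched, precision, recall);
    precision and recall are 1.0 for two empty inputs by convention.
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    i = j = matched = 0
    while i < detected.size and j < truth.size:
        d = detected[i] - truth[j]
        if abs(d) <= tol_s:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    precision = matched / detected.size if detected.size else 1.0
    recall = matched / truth.size if truth.size else 1.0
    return matched, precision, recall


def _cp_template(sample_rate: float, width_s: float, amplitude: float) -> tuple[np.ndarray, int]:
    """Biphasic pulse: positive Gaussian lobe then a delayed negative lobe.

    Returns (template, apex_offset_samples); the apex sits at the planted time.
    """
    sigma = width_s / 2.0
    delay = 2.0 * sigma
    t = np.arange(-4 * sigma, delay + 4 * sigma, 1.0 / sample_rate)
    tpl = np.exp(-(t**2) / (2 * sigma**2)) - 0.6 * np.exp(
        -((t - delay) ** 2) / (2 * sigma**2)
    )
    tpl = amplitude * tpl / tpl.max()
    return tpl, int(np.argmax(tpl))


def _rp_template(sample_rate: float, width_s: float, amplitude: float) -> tuple[np.ndarray, int]:
    sigma = width_s / 2.0
    t = np.arange(-3 * sigma, 3 * sigma, 1.0 / sample_rate)
    tpl = amplitude * np.exp(-(t**2) / (2 * sigma**2))
    return tpl, int(np.argmax(tpl))


def _add_events(clean: np.ndarray, times: np.ndarray, tpl: np.ndarray,
                apex: int, sample_rate: float) -> None:
    n = clean.size
    for t in times:
        start = int(round(t * sample_rate)) - apex
        lo, hi = max(start, 0), min(start + tpl.size, n)
        if hi > lo:
            clean[lo:hi] += tpl[lo - start : hi - start]


def simulate(config: SynthConfig, source_id: str = "sim",
             params: DetectionParams | None = None) -> tuple[RecordingSet, GroundTruth]:
    """Generate one multi-channel recording with known ground truth.

    ``params`` sets the thresholds under which the ground-truth metrics are
    evaluated (defaults to :class:`DetectionParams` defaults). Identical
    config and seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    sd = config.slowdown_factor
    intra_mean, intra_cv = config.intra_burst_interval
    if intra_mean <= 0:
        raise ParameterError("intra-burst interval mean must be positive")

    def draw_intra() -> float:
        if intra_cv <= 0:
            return intra_mean * sd
        shape = 1.0 / intra_cv**2
        return float(rng.gamma(shape, intra_mean / shape)) * sd

    if config.burst_rate > 0:
        cycle = 60.0 / config.burst_rate
        expected_burst = (config.peaks_per_burst - 1.0) * intra_mean
        gap_excess = max(cycle - expected_burst - config.min_gap_s, 0.05 * config.min_gap_s)
    else:
        gap_excess = np.inf

    def draw_gap() -> float:
        return (config.min_gap_s + float(rng.exponential(gap_excess))) * sd

    margin = 4.0 * config.cp_width_s
    cp_times: list[float] = []
    burst_ids: list[int] = []
    t = draw_gap()
    b = 0
    while t < config.duration_s - margin:
        k = 1 + int(rng.poisson(max(config.peaks_per_burst - 1.0, 0.0)))
        times = [t]
        for _ in range(k - 1):
            nxt = times[-1] + draw_intra()
            if nxt >= config.duration_s - margin:
                break
            times.append(nxt)
        cp_times.extend(times)
        burst_ids.extend([b] * len(times))
        b += 1
        t = times[-1] + draw_gap()

    cp_arr = np.asarray(cp_times)
    if cp_arr.size == 0:
        warnings.warn("duration too short for a single burst; ground truth is empty",
                      stacklevel=2)
    elif cp_arr.size > 1 and np.min(np.diff(cp_arr)) < 4.0 * config.cp_width_s:
        warnings.warn("planted events denser than the pulse template; waveforms overlap",
                      stacklevel=2)

    # rhythmic potentials: homogeneous Poisson train
    rp_times: list[float] = []
    if config.rp_amplitude > 0 and config.rp_rate_hz > 0:
        t = float(rng.exponential(1.0 / config.rp_rate_hz)) * sd
        while t < config.duration_s:
            rp_times.append(t)
            t += float(rng.exponential(1.0 / config.rp_rate_hz)) * sd
    rp_arr = np.asarray(rp_times)

    n = int(round(config.duration_s * config.sample_rate_hz))
    clean = np.zeros(n)
    if cp_arr.size:
        tpl, apex = _cp_template(config.sample_rate_hz, config.cp_width_s,
                                 config.cp_amplitude)
        _add_events(clean, cp_arr, tpl, apex, config.sample_rate_hz)
    if rp_arr.size:
        tpl, apex = _rp_template(config.sample_rate_hz, config.rp_width_s,
                                 config.rp_amplitude)
        _add_events(clean, rp_arr, tpl, apex, config.sample_rate_hz)

    if config.channel_gains is not None:
        gains = np.asarray(config.channel_gains, dtype=float)
        if gains.size != config.n_channels:
            raise ParameterError("channel_gains length must equal n_channels")
    else:
        gains = rng.lognormal(0.0, 0.4, config.n_channels)
    data = gains[:, None] * clean[None, :]
    if config.noise_sigma > 0:
        data = data + rng.normal(0.0, config.noise_sigma, data.shape)

    traces = [
        RecordingTrace(channel_id=i, sample_rate=config.sample_rate_hz,
                       samples=row, source_id=source_id)
        for i, row in enumerate(data)
    ]
    rec = RecordingSet(traces=traces,
                       metadata={"source_id": source_id, "config": config.to_dict(),
                                 "channel_gains": gains})

    true_metrics = None
    if cp_arr.size:
        p = params if params is not None else DetectionParams()
        train = PeakTrain(source_id=source_id,
                          peak_times=cp_arr - cp_arr[0],
                          final_time=config.duration_s - cp_arr[0],
                          params=p)
        true_metrics = compute_metrics(classify_intervals(train, params=p))
    truth = GroundTruth(cp_times_s=cp_arr,
                        burst_membership=np.asarray(burst_ids, dtype=int),
                        rp_times_s=rp_arr,
                        true_metrics=true_metrics)
    return rec, truth
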