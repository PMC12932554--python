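# Methods

This note documents the models, parameter choices and numerical decisions
behind `hydramea`, and what the simulator-based tests do and do not show
about real recordings.

## Signal model and detection procedure

The analyzed object is a single channel of a multi-electrode array
recording: a uniformly sampled voltage series in device-native units. The
pipeline assumes contraction pulses (CPs) are the dominant high-amplitude
events on the trace and that their waveform is slow relative to the
sampling interval, so that a 20 ms moving average suppresses noise without
erasing the pulse.

**Normalization.** The trace is divided by its maximum *absolute* value.
Extracellular deflections can be negative-going, and dividing by a signed
maximum would flip the polarity of negative-dominant traces; the absolute
convention keeps waveform polarity and still yields a unit peak magnitude.
A consequence worth knowing: the normalized height of a pulse depends on
the single largest excursion in the record, so one large artifact lowers
every event's normalized amplitude.

**Smoothing.** A length-`N` centered moving average (`average_window`,
default 200 samples = 20 ms at 10 kHz). At the record edges the window is
truncated to the available samples rather than padded, so no phantom values
enter; the filter is linear and mean-preserving in the interior.

**Derivatives.** Both derivatives are centered finite differences with step
`theta` (`time_threshold`, default 20 ms):

    f'(t_i)  = [x(t_i + θ/2) − x(t_i − θ/2)] / θ
    f''(t_i) = [f'(t_i + θ/2) − f'(t_i − θ/2)] / θ

`theta` must span an even number of sample intervals so the half-step lands
on the grid; boundary samples where a stencil exits the record are marked
unavailable (NaN) rather than extrapolated. The second derivative is the
*composition* of two first-difference stencils, not the direct three-point
second difference — slightly more noise-sensitive, but it emphasizes the
curvature transitions used for acceptance. The first operator is exact on
affine signals, the composition exact on quadratics; both are O(θ²)
otherwise (verified against analytic sine derivatives in the tests).

**Acceptance conditions.** A sample is a peak iff (a) the smoothed signal
exceeds `normalized_threshold`, (b) f' > 0, and (c) f'' crossed from
positive to ≤ 0 somewhere in the half-stencil `[t_i − θ/2, t_i]`. The
direction of the concavity transition (+ → −) is the only reading
consistent with accepting pulse tops: it fires at the inflection point of
the rising edge. Consequently the reported peak time sits slightly *before*
the waveform apex — by about one effective pulse sigma (≈ 15–20 ms for the
default pulse shapes). The accepted sample's own timestamp is reported;
sub-sample interpolation is out of scope. After each acceptance the scan
pointer jumps to `t + refractory_period`, so no sample inside the dead time
is ever evaluated and output spacing ≥ refractory period is a hard
invariant. Conditions are conjunctive, so evaluation order is unobservable;
the threshold test runs first only because it is cheapest. The scan is
greedy-earliest over the boolean acceptance mask, which maximizes the
number of accepted events under the spacing constraint — this is why the
detected count is provably non-increasing in the threshold.

**Default thresholds.** `normalized_threshold` 0.3, `theta` 20 ms,
`refractory_period` 1.0 s, `cp_threshold` = `icbi_threshold` = 10 s. These
are package defaults chosen to be sensible for Hydra-scale dynamics
(contractions seconds apart, quiescent gaps tens of seconds); they are not
calibrated against any published parameter table and every one is exposed
in the configuration file.

## Alignment, classification, metrics

Each recording is re-zeroed to its first detected peak (the pre-peak
interval is discarded) and a set of recordings is truncated to the common
window `t_last`, the minimum realigned length. Intervals between
consecutive peaks plus the terminal interval (last peak → `t_last`, taken
as a non-negative duration and classified by the same rule) tile
`[0, t_last]` exactly — conservation `CTime + ETime = t_last` holds to
1e-9 relative tolerance whenever the two thresholds are equal.

Decisions taken where the procedure was genuinely open:

* **Intermediate band.** If `cp_threshold < icbi_threshold`, intervals in
  between are labeled `ambiguous`, excluded from CTime/ETime, and warned
  about. The default sets the thresholds equal so the dichotomy is
  exhaustive.
* **Burst counting.** Bursts are counted as maximal runs of consecutive CP
  intervals. The alternative convention — increment a counter at each IcBI —
  undercounts by one when a recording ends inside a burst; nIcBI is
  reported separately so both views are available.
* **CPs per burst.** `count_convention="intervals"` (default) counts a run
  of k CP intervals as k, keeping `nCP = Σ nCPBurst` consistent with
  `CTime = Σ CPI`; `"peaks"` counts the k+1 spanning peaks instead.
* **HyAI degeneracy.** `HyAI = CTime/ETime` is flagged undefined (reported
  as infinity with `hyai_defined=False`) when ETime = 0, rather than
  raising — a fully contractile window is a meaningful observation.

## Channel selection

The literature motivating this pipeline selects the single trace with the
highest signal-to-noise ratio rather than averaging channels (averaging
would attenuate low-amplitude events below the detection threshold). SNR is
not formally defined there, so this package fixes a statistic that needs no
prior detection: peak-to-peak amplitude of the smoothed trace divided by a
robust noise scale — 1.4826·MAD of the first difference, divided by √2
because differencing doubles white-noise variance. It is invariant to
global rescaling and monotone in per-channel gain; the scorer is pluggable
for users who prefer a spectral or detection-based definition.

## Synthetic data generator

The simulator emulates what the detection stage relies on, with every shape
configurable:

* **Timing.** Burst onsets follow a renewal process: quiescent gaps are
  `min_gap_s + Exponential(mean derived from burst_rate)`; the hard floor
  (default 12 s, above the 10 s interval threshold) keeps planted bursts
  unambiguous. CPs per burst are `1 + Poisson(peaks_per_burst − 1)`;
  intra-burst intervals are gamma-distributed with configurable mean and
  CV. `slowdown_factor` multiplies every sampled interval (anesthesia
  analogue).
* **Waveforms.** CPs are biphasic templates (positive Gaussian lobe, width
  `cp_width_s`, followed by a delayed 0.6-amplitude negative lobe);
  rhythmic potentials are single wide Gaussians at low amplitude (default
  0.15, half the detection threshold — they act as structured interference,
  and are deliberately *not* detected). These shapes are modeling choices;
  amplitudes and widths are order-of-magnitude choices, not fitted to
  published waveforms.
* **Channels.** All channels share event times and differ by a
  multiplicative gain (default log-normal, σ = 0.4), plus i.i.d. Gaussian
  noise per channel — mimicking a millimeter-scale animal over a
  micrometric electrode grid.
* **Determinism.** One `numpy` Generator seeded from the config drives all
  draws in a fixed order; identical config + seed gives bit-identical
  arrays and (with HDF5 timestamps disabled) byte-identical files.

What the simulator does **not** model: electrode impedance and coupling
geometry (beyond gain), drift and movement artifacts, biphasic waveform
variability between events, non-stationary rates within a condition, and
any biophysics of the epitheliomuscular tissue. Passing recovery tests
therefore demonstrates correctness of the *algorithm* under the stated
signal model, not detection performance on arbitrary real recordings.

## Test and script problem sizes

The unit and acceptance tests run most scenarios at 1 kHz sampling with the
detection windows rescaled to the same physical durations (20 ms averaging,
20 ms derivative step), and use single-channel recordings where channel
selection is not the property under test; detection-accuracy checks run at
the native 10 kHz. Scenario durations (60–1000 s) were chosen to contain
enough burst cycles (≈ 10–25) that renewal-process edge effects stay small.
The slowdown-scenario ratio slightly exceeds the nominal interval factor
because a 4×-slowed process spends a larger fraction of a fixed window in
its initial quiescent gap; the tolerance band in the tests reflects that
renewal edge effect, not detector error.

## Known limitations

* Peak times carry a systematic pre-apex offset (inflection-point firing);
  analyses needing apex-accurate latencies should post-process with a local
  maximum search.
* Normalization by the global maximum makes detection sensitive to single
  large artifacts; no artifact rejection is included.
* The vendor HDF5 reader handles only the common nested-group layout and
  requires a `sample_rate_hz` attribute; proprietary containers are out of
  scope.
* Rhythmic potentials are generated but never detected; the package offers
  no RP detector.
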