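# hydramea

Detection, alignment and classification of **contraction pulses (CPs)** in
extracellular multielectrode-array (MEA) recordings of whole small organisms
(*Hydra vulgaris*), with a synthetic-signal simulator so every stage of the
pipeline can be tested against exact ground truth.

## The problem

A *Hydra* coupled to a planar MEA produces large, synchronous field
potentials during body contractions. These contraction pulses arrive in
rhythmic **contraction bursts (CBs)** separated by long quiescent
**inter-contraction burst intervals (IcBIs)** during which the animal
elongates. Because the animal dwarfs the micrometric electrodes, absolute
amplitudes vary wildly across the 60 channels while event *times* are
shared — so detection must rely on temporal and morphological features, not
absolute voltage. This package implements that pipeline for
electrophysiologists quantifying whole-animal behavioral state from MEA
data, and for anyone needing a reproducible, simulator-backed burst-analysis
toolchain.

## The method

For one selected channel (the highest-SNR trace of the array) with amplitude
vector $S$ sampled at rate $f_s$:

1. **Normalize**: $S_{\mathrm{norm}} = S / \max|S|$ — thresholds become
   fractions of the recording's own dynamic range.
2. **Smooth**: centered moving average over $N$ samples (the *Average
   Threshold*, default $N = 200$, i.e. 20 ms at 10 kHz).
3. **Differentiate** with centered finite differences over a time window
   $\theta$ (the *Time Threshold*, default 20 ms):
   $f'(t_i) = \dfrac{x(t_i + \theta/2) - x(t_i - \theta/2)}{\theta}$,
   and $f''$ as the same stencil applied to the $f'$ values (deliberately a
   composition, not the direct three-point second difference).
4. **Detect**: accept sample $t_i$ as a CP peak iff the smoothed signal
   exceeds the *Normalized Threshold*, $f'(t_i) > 0$, and $f''$ has just
   crossed from positive to negative (concavity transition); then skip
   ahead by the *Refractory Period*.
5. **Align and window**: each recording is re-zeroed to its first peak,
   $t_{r,q} = t_{i,q} - t_{1,q}$, and all recordings are truncated to the
   common window $t_{\mathrm{last}} = \min_q t_{\mathrm{final},q}$.
6. **Classify intervals**: each inter-peak interval
   $\delta_{p,q} = t_{p+1,q} - t_{p,q}$ (plus the terminal interval up to
   $t_{\mathrm{last}}$) is a **CP interval** if $\delta <$ *CP Threshold*,
   else an **IcBI**. Bursts are maximal runs of CP intervals.
7. **Quantify**: per recording — CP interval durations (CPI) and their sums
   per burst (BurstTime) and per file (CTime); IcBI durations and their sum
   (ETime); counts nBurst, nIcBI, nCP, nCPBurst; and the activity index

$$\mathrm{HyAI} = \frac{\sum_i \Delta \mathrm{CP}_i}{\sum_j \Delta \mathrm{IcBI}_j} \equiv \frac{C_{\mathrm{Time}}}{E_{\mathrm{Time}}},$$

the balance between contractile and elongation behavior. Reporting helpers
add per-condition descriptive statistics (mean, SD, coefficient of
variation $\sigma^* = \sigma/|\mu|$, quartiles, 5th/95th percentiles),
Welch t-tests and a standardized PCA over {CTime, ETime, nBurst, nCP}.

## Worked example

```python
import numpy as np
from hydramea import (SynthConfig, simulate, select_best_channel, preprocess,
                      DetectionParams, detect_peaks, align_and_window,
                      classify_intervals, compute_metrics)

cfg = SynthConfig(duration_s=300.0, sample_rate_hz=1000.0, n_channels=8,
                  burst_rate=2.0, peaks_per_burst=5.0,
                  intra_burst_interval=(1.5, 0.25), noise_sigma=0.15, seed=42)
rec, truth = simulate(cfg, source_id="demo")

params = DetectionParams(average_window=20, time_threshold=0.02,
                         refractory_period=0.5)
ch = select_best_channel(rec)
train = detect_peaks(preprocess(rec.traces[ch], params.average_window), params)
aligned = align_and_window([train])
metrics = compute_metrics(classify_intervals(aligned.trains[0], params=params))
```

Output:

```
best channel          : 2
planted / detected CPs: 47 / 47
common window t_last  : 259.166 s
nBurst = 8, nCP = 39, nIcBI = 8
CTime = 57.277 s, ETime = 201.889 s
HyAI  = 0.284   (ground truth 0.284)
```

All 47 planted pulses are recovered on the channel the SNR ranking picked
(the one simulated with the largest gain). The analysis window starts at the
first detected pulse (≈ 41 s into the recording), 57 s of it is spent inside
contraction bursts versus 202 s quiescent, giving HyAI ≈ 0.28 — identical to
the value implied by the planted ground-truth times.

The same pipeline is available from a shell:

```bash
hydramea simulate --config config.yaml --out runs/ctrl -n 5
hydramea detect  'runs/ctrl/*.h5'        --config config.yaml --out runs/ctrl_det
hydramea metrics 'runs/ctrl_det/*_peaks.csv' --out runs/ctrl_met
hydramea compare runs/ctrl_met runs/drug_met --label-a ctrl --label-b drug \
    --out runs/cmp --plots
```

Every command archives its effective configuration (`config_used.yaml`)
next to its outputs; re-running with it reproduces results bit-for-bit.

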