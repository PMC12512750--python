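# mwicp

**Machine-learning pipeline for noninvasive intracranial-pressure (ICP)
estimation from microwave S-parameter sweeps.**

Elevated intracranial pressure is a key indicator of neurological injury,
but the reference measurement techniques are invasive (ventricular
catheters, lumbar puncture) and unsuited to prolonged or wearable
monitoring. A promising noninvasive alternative places a pair of small
planar microwave antennas on the scalp: volume changes inside the skull
alter the effective dielectric profile of the head, which shifts the
amplitude, resonance frequency and phase of the sensor pair's scattering
parameters. `mwicp` implements the full signal-processing and learning
chain that turns time-ordered two-port sweeps — reflection S_XX and
transmission S_XY, magnitude and phase versus frequency — plus a
synchronized invasive reference pressure stream into a quantitative ICP
estimate, together with a forward simulator of pressure-coupled phantom
measurement trials for development and validation.

## The method

For each trial the pipeline performs, in order:

1. **Alignment** — each sweep's reference pressure is the mean of the
   5 kHz invasive stream over the sweep's acquisition window, paired via
   the trigger log.
2. **Cleaning (ζ₁)** — every (channel, frequency-bin) time series is a
   *data string*: outliers are flagged by a Hampel rule (window median ±
   3·MAD, window 11) and replaced by the window median; strings are
   z-scored for reporting while features use the cleaned physical units.
3. **Band optimization** — per frequency bin, the temporal range
   max_t − min_t of |S_XX| is computed; the optimal frequency f_opt is the
   bin of maximal range, and the optimal band is the closed interval
   [f_opt − f_th, f_opt + f_th] with f_th = 50 MHz (51 bins on the 2 MHz
   instrument grid).
4. **Time limiting (ζ₂)** — sweeps before pump onset (centred slope of
   pressure ≤ 0.1 mmHg/s) and after the pressure first reaches its
   maximum are dropped; the quiescent lead sweeps are kept as the
   baseline for differential features.
5. **Dataset variants** — each trial yields four overlapping windows:
   Ds₁ (all samples), Ds₂ (first 80 %), Ds₃ (last 80 %), Ds₄ (middle
   80 %), which stabilizes the correlation analysis against badly
   captured trial edges.
6. **Two-level features** — twelve per-sweep series a–l over the band:
   minima of |S_XX|, |S_XY|; AUC of |S_XX|, |S_XY|; AUC of the group
   delay distortion GDD(∠S_XX), GDD(∠S_XY) where
   τ(f) = −(1/2π)·dφ/df and GDD = τ − mean_band(τ); AUC of the
   differential multistatic data matrix MDM_D and of its RMS reduction
   MDM_RMS; and the percent amplitude of fluctuation
   PerAF = 100·mean|x − µ|/|µ| of both magnitudes and phases.
7. **OSS (Ordered Selection Scheme)** — features are scored by Pearson
   correlation r with the reference pressure, ordered by |r| and kept if
   |r| > 0.8 with p < 0.001.
8. **Regression** — a fixed zoo of 25 presets (linear models, decision
   trees, SVMs, tree ensembles, Gaussian processes, neural networks and
   kernel models) maps the selected features to pressure. Training,
   five-fold cross-validation and evaluation are *trial-disjoint*: all
   samples of one trial live on one side of every split (80/10/10
   train/validation/test by trial count). Models are compared by MAE,
   RMSE and R².

Because no measurement data are distributed with this package, the
`synth` module provides a forward simulator: sensor-specific baseline
resonance profiles for six sensor pairs (A–F), a pump-driven pressure
trajectory (0→60 mmHg ramp with 60 bpm pulsation, sampled at 5 kHz) and a
linear pressure-to-S-parameter coupling with VNA trace noise of
5×10⁻³ dB RMS, swept 2–6 GHz at 2001 points and 3 Hz.

## Worked example

Run a reduced campaign for sensor A (two placements, five repeated trials
each, 40 s ramps):

```sh
$ mwicp run --sensors A --placements 20mm,10mm --duration 40 --seed 123
480 feature records
A: best=Robust Linear MAE=0.010 RMSE=0.012 R2=1.00000
```

The 10 trials × 4 variants × 12 classes give 480 feature records; the
best preset on the validation trial is then scored on the held-out test
trial, here recovering the 0–60 mmHg ramp with a mean absolute error of
0.01 mmHg. Individual stages are available too:

```sh
$ mwicp simulate --sensor A --duration 20 --seed 7 --out demo_trial
wrote 60 sweeps; manifest: demo_trial/manifest.yaml
$ mwicp preprocess demo_trial/manifest.yaml
band 3.536-3.636 GHz around f_opt=3.586 GHz; 41 sweeps kept (onset at sweep 19)
```

The selected band straddles sensor A's resonance dip (−35.3 dB at
3.565 GHz); the 19 discarded sweeps are the pre-pump lead segment.
Trials are stored as one Touchstone `.s2p` file per sweep plus a
reference CSV and a YAML manifest, so externally recorded data can be
ingested through the same path.

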