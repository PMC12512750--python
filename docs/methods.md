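# Methods

This note records the models, numerical choices and limitations behind
`mwicp`, at the level of detail a maintainer needs to change them safely.

## Measurement model and simulator

The physical system is a two-antenna microwave sensor on the scalp of a
head phantom whose internal pressure is driven by a dosing pump. The
simulator (`mwicp.synth`) is a phenomenological forward model, not an
electromagnetic solver; it reproduces the *statistical structure* the
pipeline relies on, with these components:

**Baseline sensor profiles.** Each sensor A–F has parametric magnitude
curves: a flat matching level plus Lorentzian dips
`-depth / (1 + ((f - f0)/w)^2)`, with dip locations and depths fixed at
the documented on-phantom values (e.g. sensor A: |S_XX| minimum
−35.3 dB at 3.565 GHz; sensor B: |S_XY| minimum −65.87 dB at 3.604 GHz).
A Lorentzian is the minimal resonance shape with a controllable Q; only
the minima are constrained by observation, the rest of the curve is a
modelling choice. Phases are a linear electrical delay (1.2 ns) plus an
arctangent signature across the reflection resonance, kept unwrapped
internally and wrapped only on file export so the unwrapping path in the
feature stage is exercised.

**Pressure trajectory.** A flat pre-pump lead (default 5 s at 0 mmHg),
then a monotone ramp to 60 mmHg with a superimposed zero-mean
raised-cosine pulsation at 60 bpm (default peak-to-peak 2 mmHg), sampled
at 5 kHz with the endpoint sample included so the ramp attains its target
exactly. Two seeded jitters differentiate repeated trials, because real
pump runs never repeat exactly: the ramp follows `x**gamma` with
`log(gamma)` uniform in ±0.15, and the pump start shifts uniformly by up
to 2 s. Both are monotonicity-preserving and can be zeroed for exactly
linear, exactly timed ramps. The pulsation is gauge-zero-mean per beat;
near the ramp foot this admits ~1 mmHg negative excursions (pressure is
gauge pressure relative to atmosphere).

**Coupling.** Pressure acts linearly on the baseline in three ways:
an amplitude offset `alpha * p` with a Gaussian spectral shape
(σ = 50 MHz) centred on the resonance, a resonance shift `beta * p`
applied by re-evaluating the parametric baseline at shifted frequencies,
and a flat phase offset `gamma * p`. Defaults are
alpha = −0.05 dB/mmHg, beta = 0.05 MHz/mmHg, gamma = 0.003 rad/mmHg.
**These coupling magnitudes are synthetic**: no quantitative
dB-per-mmHg coefficients exist for the physical setup, so they were
chosen once such that the planted pressure dependence clearly dominates
the instrument noise floor (about 3 dB of dip modulation over the 60 mmHg
range against 5×10⁻³ dB RMS trace noise), and are documented as simulator
defaults rather than measured values. Each sweep is coupled to the
reference pressure averaged over its acquisition window, mirroring the
fact that a VNA integrates over its sweep interval.

**What the simulator does not emulate:** antenna electromagnetics,
phantom dielectric spectra, cable strain, temperature drift of the
instrument, motion artifacts, or inter-subject anatomical variability.
Passing tests on simulated campaigns therefore demonstrate the
correctness and statistical soundness of the *pipeline* — not the
clinical performance of any physical sensor.

## Preprocessing choices

- **Hampel parameters** (window 11, k = 3, raw MAD without the Gaussian
  consistency factor) are implementation choices; the cleaning stage is
  named in the protocol but its parameters are not specified anywhere.
  The MAD of each window is taken about that window's own median.
- **Normalization** is per data string (z-score; zero-variance strings
  map to zeros). Feature extraction operates on the outlier-cleaned
  *physical* values: Pearson correlation is affine-invariant, so
  normalization does not change the selection stage, and physical units
  keep the regression targets interpretable.
- **Band statistic.** The "maximum deviation" statistic is read as: per
  frequency bin, the temporal range (max − min over sweeps) of |S_XX|,
  maximized over bins, ties toward the lowest frequency. An alternative
  reading — the range of per-sweep *minimum values*, grouped by their
  located bin — is available via `optimal_frequency(..., variant=
  "located-minima")` but is undefined whenever minima never revisit a
  bin, which is why it is not the default. The S_XX-derived band is
  applied to all four channels; transmission gets no separate band.
- **Onset detection** uses a centred least-squares slope over ±2 sweeps
  with a 0.1 mmHg/s threshold. A centred window looks slightly ahead, so
  onset can land up to two sweeps before the first truly ramping sweep;
  this only moves a sweep or two of quiescent data into the retained
  window and is harmless downstream.
- **Sub-bin extremum refinement.** Resonance dips generally fall between
  grid lines (a 2 MHz grid cannot represent odd multiples of 1 MHz), so
  reported dip locations use three-point parabolic vertex interpolation
  around the discrete argmin. For a symmetric dip sampled symmetrically
  this recovers the true centre exactly. Band selection itself stays on
  grid bins.

## Feature definitions

The four Level-2 primitives follow their standard literature forms, each
isolated behind its own function so a different convention can be swapped
in:

- **MDM_D**: per sweep and bin, the two-port matrix minus the
  element-wise mean of a quiescent baseline window (first 5 pre-onset
  sweeps when the trial has a lead segment, else the first 5 processed
  sweeps), reduced per bin by the norm over the *distinct* measured
  channels, `sqrt(dSxx² + dSxy²)`. Duplicating the reciprocal matrix
  entries would only multiply every value by √2; excluding them keeps a
  single-channel step of d dB at exactly d.
- **MDM_RMS**: RMS of the MDM_D curve over band bins, per sweep. The
  feature class h applies a 5-sweep centred moving trapezoidal integral
  over time to this scalar series, which distinguishes it from class g
  (the per-sweep frequency-axis AUC of MDM_D).
- **GDD**: group delay τ(f) = −(1/2π)·dφ/df by central differences
  (second-order accurate at the edges), minus its band mean. Summarized
  by the AUC of |GDD|. Invariant to constant phase offsets by
  construction.
- **PerAF**: 100·mean|x − µ|/|µ| with µ the band mean of one sweep's
  curve; scale-invariant, undefined (masked NaN) when µ = 0.

All per-sweep features integrate or scan along the *frequency* axis
within the optimal band, producing time series correlatable with
pressure. AUC units are GHz·dB or GHz·rad accordingly.

## Selection and regression

- Correlation strength bins follow the printed boundary semantics
  exactly: 0.8 itself is "strong", not "very strong"; OSS selection
  requires |r| *strictly* above the threshold.
- A significance gate excludes features with p ≥ 0.001 regardless of
  |r| (configurable; the protocol quotes both 0.001 and 0.05 in
  different places, and the stricter value is the default). No
  multiple-testing correction is applied, deliberately.
- When one class set must serve a whole campaign, per-class scores are
  the median r over trials and variants (median preserves the sign of a
  consistently-signed class and resists the occasional badly captured
  trial).
- The regression catalog fixes 25 presets: 3 linear, 3 trees (leaf sizes
  4/12/36), 6 SVMs (linear, quadratic, cubic, fine/medium/coarse
  Gaussian with kernel scale ∝ √P/4, √P, 4√P), boosted and bagged trees,
  4 GP kernels (squared exponential, Matérn 5/2, exponential, rational
  quadratic, each plus a white-noise term, normalized targets, no
  optimizer restarts), 5 MLPs (10/25/100/10-10/10-10-10, LBFGS, up to
  2000 iterations) and 2 Nystroem kernel models (linear SVR and ridge
  heads). Hyperparameters beyond the preset names are package defaults;
  exact parity with any external implementation of these presets is not
  claimed. There is no hyperparameter search.
- R² is computed on the test set against the test mean; a zero-variance
  test target is reported as R² = 0 with a degeneracy flag. MAE ≤ RMSE
  is asserted as an invariant on every report.
- Cross-validation folds, like the 80/10/10 split, partition *trials*,
  never samples; fold assignment is a seeded round-robin over shuffled
  trial ids, so it is deterministic under the run seed.
- Dataset-variant boundaries use round-half-up on sample counts with
  1-based inclusive ranges. The middle window starts after the first
  round(0.1·N) samples and retains exactly round(0.8·N) samples —
  rounding its two endpoints independently would break the equal-length
  property at some N (first seen at N = 13).

## Problem sizes

Unit tests run on coarse grids (41–201 points) and short trials. The
end-to-end campaign tests use a 501-point grid with 24 s ramps for the
six-sensor bookkeeping campaign (150 trials) and the full 2001-point
grid with 40 s ramps and the complete 25-preset zoo for the
single-sensor recovery campaign (10 trials); these sizes keep a full
suite run at a few minutes on one core while preserving every
statistical default (coupling, noise, band half-width, thresholds,
split fractions). Lab-scale 120 s trials are the simulator default.

## Known limitations

- Touchstone support covers the 2-port dB/angle, magnitude/angle and
  real/imaginary dialects with frequency-unit scaling; exotic option-line
  features (non-50 Ω references, noise parameters) are out of scope.
- The simulated S_XY phase carries no resonance signature, so feature
  class f (AUC of GDD over the transmission phase) is uninformative on
  synthetic data — a realistic outcome (not every class correlates), but
  one to remember when interpreting synthetic campaign summaries.
- `average_trials` truncates to the shortest trial; with trials of very
  different onset latencies this discards data rather than re-aligning
  by pressure level.
- Invasive-sensor drift correction, smoothing beyond the Hampel rule,
  and learned/embedding features are deliberately absent.
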