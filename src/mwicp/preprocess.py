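"""Preprocessing: cleaning, band optimization and time limiting.

The cleaning step treats every (channel, frequency-bin) time series as one
"data string": outliers are flagged by a Hampel rule (window median +/- 3
MAD over an 11-sample window) and replaced by the window median, then each
string is z-score normalized for reporting while the outlier-cleaned raw
dB/radian curves are retained for feature extraction (the downstream
correlation statistic is affine-invariant, so features operate on physical
units).

Band optimization finds the frequency bin whose reflection magnitude shows
the largest temporal excursion over the trial and keeps a +/- f_th window
around it (f_th defaults to 50 MHz); the reflection-derived band is applied
to all four channels. Time limiting drops leading sweeps before pump onset
and trailing sweeps after the pressure first reaches its maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import (
    CHANNELS,
    AlignedTrial,
    DegenerateInputError,
    FrequencyGrid,
)

__all__ = [
    "BandSelection",
    "ProcessedTrial",
    "zeta1_clean",
    "hampel_mask",
    "locate_minima",
    "refine_minimum",
    "optimal_frequency",
    "optimal_band",
    "zeta2_limit",
    "process_trial",
    "average_trials",
]

_FTOL = 1e-9  # GHz tolerance for closed-interval grid membership


@dataclass
class BandSelection:
    """Optimal band around the frequency of maximal temporal variation."""

    f_opt_ghz: float
    f_th_mhz: float
    indices: np.ndarray
    f_lo_ghz: float
    f_hi_ghz: float
    loc_per_sweep: np.ndarray | None = None
    val_per_sweep: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.indices)


@dataclass
class ProcessedTrial:
    """Cleaned, band- and time-limited trial ready for feature extraction."""

    sensor_id: str
    trial_index: int
    placement: str
    freqs_ghz: np.ndarray          # band frequencies
    channels: dict[str, np.ndarray]  # (n_sweeps, n_band_bins) cleaned raw
    p_at_sweep: np.ndarray
    t_at_sweep: np.ndarray
    band: BandSelection
    onset_index: int
    end_index: int
    normalization: dict[str, dict[str, np.ndarray]]
    pre_onset: dict[str, np.ndarray] | None = None  # band-limited lead sweeps

    @property
    def n_sweeps(self) -> int:
        return len(self.p_at_sweep)


def hampel_mask(series: np.ndarray, window: int = 11, k: float = 3.0):
    """Hampel outlier rule along axis 0: |x - med| > k * MAD.

    Returns (mask, medians) where medians are the rolling window medians
    used for replacement. Works on 1-D strings or 2-D (time x bins) arrays.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("empty series")
    half = window // 2
    pad = ((half, half),) + ((0, 0),) * (x.ndim - 1)
    padded = np.pad(x, pad, mode="edge")
    windows = sliding_window_view(padded, window, axis=0)
    med = np.median(windows, axis=-1)
    mad = np.median(np.abs(windows - med[..., None]), axis=-1)
    mask = np.abs(x - med) > k * mad
    return mask, med


def zeta1_clean(series: np.ndarray, window: int = 11, k: float = 3.0):
    """Clean and normalize data strings (outlier replacement + z-score).

    ``series`` is one string (1-D over time) or a stack of strings
    (2-D, time on axis 0). Returns a dict with ``cleaned`` (raw units,
    outliers replaced by the window median), ``normalized`` (z-scored per
    string; all-zero for zero-variance strings), ``mask``, ``center`` and
    ``scale``.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("empty series")
    mask, med = hampel_mask(x, window=window, k=k)
    cleaned = np.where(mask, med, x)
    center = cleaned.mean(axis=0)
    scale = cleaned.std(axis=0)
    safe = np.where(scale == 0, 1.0, scale)
    normalized = (cleaned - center) / safe
    normalized = np.where(scale == 0, 0.0, normalized)
    return {
        "cleaned": cleaned,
        "normalized": normalized,
        "mask": mask,
        "center": center,
        "scale": scale,
    }


def locate_minima(mag_db: np.ndarray, grid: FrequencyGrid):
    """Per-sweep location and value of the global magnitude minimum.

    Ties break toward the lowest frequency. Returns
    ``(loc_per_sweep_ghz, val_per_sweep_db)``.
    """
    mag = np.atleast_2d(np.asarray(mag_db, dtype=float))
    if mag.shape[0] < 1 or mag.shape[1] < 1:
        raise DegenerateInputError("need at least one sweep and one bin")
    idx = np.argmin(mag, axis=1)  # first occurrence = lowest frequency
    freqs = grid.frequencies_ghz
    return freqs[idx], mag[np.arange(mag.shape[0]), idx]


def refine_minimum(curve_db: np.ndarray, freqs_ghz: np.ndarray):
    """Sub-bin minimum location by three-point parabolic interpolation.

    The discrete argmin and its two neighbours define a parabola whose
    vertex estimates the continuous minimum; resonances generally fall
    between grid bins (the standard 2 MHz grid cannot represent e.g. an
    odd multiple of 1 MHz), so reported dip locations use this refinement.
    At grid edges, or when the parabola degenerates, the grid minimum is
    returned unchanged.
    """
    y = np.asarray(curve_db, dtype=float)
    i = int(np.argmin(y))
    if i == 0 or i == len(y) - 1:
        return float(freqs_ghz[i]), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2.0 * b + c
    if denom <= 0:
        return float(freqs_ghz[i]), float(y[i])
    delta = 0.5 * (a - c) / denom
    step = freqs_ghz[i + 1] - freqs_ghz[i]
    loc = float(freqs_ghz[i] + delta * step)
    val = float(b - 0.125 * (a - c) * delta)
    return loc, val


def optimal_frequency(mag_db: np.ndarray, grid: FrequencyGrid,
                      variant: str = "per-bin-range") -> float:
    """Frequency whose magnitude varies most over the trial.

    Default reading: for every bin take the temporal range (max - min over
    sweeps) of the magnitude and return the bin with the largest range
    (ties toward the lowest frequency). The alternative
    ``variant="located-minima"`` instead tracks the per-sweep minimum
    values grouped by their located bin and maximizes the range of those
    values; it is undefined when no bin hosts the minimum more than once.
    """
    mag = np.atleast_2d(np.asarray(mag_db, dtype=float))
    if mag.shape[0] < 2:
        raise DegenerateInputError("need at least two sweeps")
    freqs = grid.frequencies_ghz
    if variant == "per-bin-range":
        ranges = mag.max(axis=0) - mag.min(axis=0)
        if np.all(ranges == 0):
            raise DegenerateInputError("magnitudes constant over the trial")
        return float(freqs[int(np.argmax(ranges))])
    if variant == "located-minima":
        idx = np.argmin(mag, axis=1)
        vals = mag[np.arange(mag.shape[0]), idx]
        best_f, best_range = None, 0.0
        for bin_id in np.unique(idx):
            group = vals[idx == bin_id]
            if len(group) < 2:
                continue
            r = float(group.max() - group.min())
            if r > best_range:
                best_range, best_f = r, float(freqs[bin_id])
        if best_f is None or best_range == 0.0:
            raise DegenerateInputError(
                "located-minima variant undefined: no revisited bin varies")
        return best_f
    raise ValueError(f"unknown variant {variant!r}")


def optimal_band(f_opt_ghz: float, f_th_mhz: float,
                 grid: FrequencyGrid) -> BandSelection:
    """Closed interval [f_opt - f_th, f_opt + f_th] intersected with the grid."""
    if f_th_mhz <= 0:
        raise DegenerateInputError("f_th must be positive")
    half = f_th_mhz * 1e-3
    freqs = grid.frequencies_ghz
    f_lo = max(grid.f_start_ghz, f_opt_ghz - half)
    f_hi = min(grid.f_stop_ghz, f_opt_ghz + half)
    indices = np.nonzero(
        (freqs >= f_lo - _FTOL) & (freqs <= f_hi + _FTOL))[0]
    return BandSelection(
        f_opt_ghz=f_opt_ghz, f_th_mhz=f_th_mhz, indices=indices,
        f_lo_ghz=f_lo, f_hi_ghz=f_hi)


def detect_onset(p_at_sweep: np.ndarray, sweep_rate_hz: float,
                 threshold_mmhg_per_s: float = 0.1,
                 slope_halfwin: int = 2) -> int:
    """First sweep whose centred slope estimate exceeds the threshold.

    The slope at sweep k is the least-squares slope of the pressure over
    the window [k - slope_halfwin, k + slope_halfwin] (truncated at the
    edges).
    """
    p = np.asarray(p_at_sweep, dtype=float)
    dt = 1.0 / sweep_rate_hz
    n = len(p)
    for k in range(n):
        a = max(0, k - slope_halfwin)
        b = min(n, k + slope_halfwin + 1)
        if b - a < 2:
            continue
        t = np.arange(a, b) * dt
        slope = np.polyfit(t, p[a:b], 1)[0]
        if slope > threshold_mmhg_per_s:
            return k
    raise DegenerateInputError("pressure never changes: no onset found")


def zeta2_limit(aligned: AlignedTrial, band: BandSelection,
                cleaned: dict[str, np.ndarray] | None = None,
                normalization: dict | None = None,
                onset_threshold: float = 0.1,
                slope_halfwin: int = 2) -> ProcessedTrial:
    """Band- and time-limit an aligned trial.

    Keeps band bins only, drops leading sweeps before pump onset and
    trailing sweeps after the pressure first attains its maximum. The
    band-limited lead sweeps are retained separately as the quiescent
    baseline for differential features.
    """
    trial = aligned.trial
    if cleaned is None:
        cleaned = {name: trial.channel(name) for name in CHANNELS}
    onset = detect_onset(aligned.p_at_sweep, trial.sweep_rate_hz,
                         onset_threshold, slope_halfwin)
    p = aligned.p_at_sweep
    end = int(np.argmax(p))  # first sweep attaining the maximum
    if end < onset:
        raise DegenerateInputError("pressure maximum precedes onset")
    idx = band.indices
    channels = {}
    pre = {}
    for name in CHANNELS:
        arr = cleaned[name]
        if "phase" in name:
            arr = np.unwrap(arr, axis=1)
        channels[name] = arr[onset:end + 1, idx]
        pre[name] = arr[:onset, idx]
    return ProcessedTrial(
        sensor_id=trial.sensor_id,
        trial_index=trial.trial_index,
        placement=trial.placement,
        freqs_ghz=trial.grid.frequencies_ghz[idx],
        channels=channels,
        p_at_sweep=p[onset:end + 1],
        t_at_sweep=aligned.t_at_sweep[onset:end + 1],
        band=band,
        onset_index=onset,
        end_index=end,
        normalization=normalization or {},
        pre_onset=pre if onset > 0 else None,
    )


def process_trial(aligned: AlignedTrial, f_th_mhz: float = 50.0,
                  hampel_window: int = 11, hampel_k: float = 3.0,
                  onset_threshold: float = 0.1,
                  band_variant: str = "per-bin-range") -> ProcessedTrial:
    """Full preprocessing chain: clean, select band, band/time-limit."""
    trial = aligned.trial
    cleaned, norm = {}, {}
    for name in CHANNELS:
        res = zeta1_clean(trial.channel(name), window=hampel_window,
                          k=hampel_k)
        cleaned[name] = res["cleaned"]
        norm[name] = {"center": res["center"], "scale": res["scale"],
                      "outliers": res["mask"].sum(axis=0)}
    loc, val = locate_minima(cleaned["sxx_mag"], trial.grid)
    f_opt = optimal_frequency(cleaned["sxx_mag"], trial.grid,
                              variant=band_variant)
    band = optimal_band(f_opt, f_th_mhz, trial.grid)
    band.loc_per_sweep, band.val_per_sweep = loc, val
    return zeta2_limit(aligned, band, cleaned=cleaned, normalization=norm,
                       onset_threshold=onset_threshold)


def average_trials(trials: list[ProcessedTrial]):
    """Element-wise mean and SEM across repeated trials of one configuration.

    Trials are truncated to the shortest sweep count; anything other than
    the nominal five repetitions triggers a warning but proceeds. Returns
    ``(mean_channels, sem_channels, mean_p, sem_p)``.
    """
    if not trials:
        raise DegenerateInputError("no trials to average")
    first = trials[0]
    for t in trials[1:]:
        if (t.sensor_id != first.sensor_id
                or t.placement != first.placement
                or t.band.n_bins != first.band.n_bins):
            raise ValueError("trials must share sensor, placement and band")
    n = len(trials)
    if n != 5:
        warnings.warn(f"averaging {n} trials (nominal repetition count is 5)")
    length = min(t.n_sweeps for t in trials)
    mean_ch, sem_ch = {}, {}
    for name in CHANNELS:
        stack = np.stack([t.channels[name][:length] for t in trials])
        mean_ch[name] = stack.mean(axis=0)
        sem_ch[name] = (stack.std(axis=0, ddof=1) / np.sqrt(n)
                        if n > 1 else np.zeros_like(stack[0]))
    pstack = np.stack([t.p_at_sweep[:length] for t in trials])
    mean_p = pstack.mean(axis=0)
    sem_p = (pstack.std(axis=0, ddof=1) / np.sqrt(n)
             if n > 1 else np.zeros_like(mean_p))
    return mean_ch, sem_ch, mean_p, sem_p
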