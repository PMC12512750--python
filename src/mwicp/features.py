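"""Two-level per-sweep feature extraction over the optimal band.

Level 1 descriptors act directly on the band-limited magnitude/phase
curves of one sweep: extrema with located frequencies, and the area under
the curve (AUC). Level 2 descriptors act on derived quantities:

MDM_D
    Differential multistatic data matrix: the two-port matrix of one sweep
    minus the element-wise mean of a quiescent baseline window, reduced to
    a per-bin curve by the norm over the distinct measured channels.
MDM_RMS
    RMS of the MDM_D curve over the band, one scalar per sweep.
GDD
    Group delay distortion: deviation of the group delay
    tau(f) = -(1/2pi) dphi/df from its band mean; summarized per sweep by
    the AUC of |distortion|.
PerAF
    Percent amplitude of fluctuation: mean absolute deviation of the curve
    as a percentage of the band mean, per sweep.

Each of the twelve feature classes a-l is a per-sweep time series aligned
with the reference pressure, which is what the downstream correlation and
regression stages consume.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import DegenerateInputError
from .datasets import DatasetVariant, create_variants
from .preprocess import ProcessedTrial, refine_minimum

__all__ = [
    "FEATURE_CLASSES",
    "level1_extrema",
    "auc",
    "mdm_d",
    "mdm_rms",
    "group_delay",
    "gdd",
    "peraf",
    "extract_features",
    "extract_feature_table",
]

# class id -> (level, channel label) in the fixed catalog order
FEATURE_CLASSES = {
    "a": (1, "min|S_XX|"),
    "b": (1, "min|S_XY|"),
    "c": (1, "AUC|S_XX|"),
    "d": (1, "AUC|S_XY|"),
    "e": (2, "AUC[GDD angS_XX]"),
    "f": (2, "AUC[GDD angS_XY]"),
    "g": (2, "AUC[MDM_D]"),
    "h": (2, "AUC[MDM_RMS]"),
    "i": (2, "PerAF|S_XX|"),
    "j": (2, "PerAF|S_XY|"),
    "k": (2, "PerAF angS_XX"),
    "l": (2, "PerAF angS_XY"),
}


def level1_extrema(curve: np.ndarray, freqs_ghz: np.ndarray,
                   refine: bool = False):
    """Min and max of one band-limited curve with located frequencies.

    Ties break toward the lowest frequency. With ``refine`` the minimum
    location/value are polished by parabolic sub-bin interpolation.
    Returns ``(min_val, min_loc, max_val, max_loc)``.
    """
    y = np.asarray(curve, dtype=float)
    if y.size == 0:
        raise DegenerateInputError("empty curve")
    imin = int(np.argmin(y))
    imax = int(np.argmax(y))
    min_val, min_loc = float(y[imin]), float(freqs_ghz[imin])
    if refine:
        min_loc, min_val = refine_minimum(y, freqs_ghz)
    return min_val, min_loc, float(y[imax]), float(freqs_ghz[imax])


def auc(curve: np.ndarray, freqs_ghz: np.ndarray) -> float | np.ndarray:
    """Trapezoidal area under the curve over the band's frequency axis.

    Accepts one curve or a (n_sweeps, n_bins) stack; the last axis is
    integrated.
    """
    y = np.asarray(curve, dtype=float)
    if y.shape[-1] < 2:
        raise DegenerateInputError("AUC needs at least two points")
    return np.trapezoid(y, freqs_ghz, axis=-1)


def mdm_d(sxx_mag: np.ndarray, sxy_mag: np.ndarray,
          baseline_count: int = 5,
          baseline: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Differential multistatic data matrix, reduced per bin.

    The quiescent baseline is the element-wise mean of the first
    ``baseline_count`` sweeps (or an explicit pre-onset window). Per sweep
    and bin the reduction is the norm over the distinct measured channels,
    ``sqrt(dSxx^2 + dSxy^2)``, so a step on one channel alone passes
    through with its own magnitude.
    """
    xx = np.atleast_2d(np.asarray(sxx_mag, dtype=float))
    xy = np.atleast_2d(np.asarray(sxy_mag, dtype=float))
    if baseline is not None:
        base_xx = np.atleast_2d(baseline[0]).mean(axis=0)
        base_xy = np.atleast_2d(baseline[1]).mean(axis=0)
    else:
        if xx.shape[0] < baseline_count + 1:
            raise DegenerateInputError(
                f"need more than baseline_count={baseline_count} sweeps")
        base_xx = xx[:baseline_count].mean(axis=0)
        base_xy = xy[:baseline_count].mean(axis=0)
    dxx = xx - base_xx
    dxy = xy - base_xy
    return np.sqrt(dxx ** 2 + dxy ** 2)


def mdm_rms(mdm_curves: np.ndarray) -> np.ndarray:
    """RMS over band bins of the MDM_D curve, one scalar per sweep."""
    m = np.atleast_2d(np.asarray(mdm_curves, dtype=float))
    if m.shape[-1] == 0:
        raise DegenerateInputError("empty band")
    return np.sqrt(np.mean(m ** 2, axis=-1))


def group_delay(phase_rad: np.ndarray, freqs_ghz: np.ndarray) -> np.ndarray:
    """Group delay tau(f) = -(1/2pi) dphi/df (ns), central differences."""
    ph = np.atleast_2d(np.asarray(phase_rad, dtype=float))
    if ph.shape[-1] < 3:
        raise DegenerateInputError("group delay needs at least 3 points")
    return -np.gradient(ph, freqs_ghz, axis=-1,
                        edge_order=2) / (2.0 * np.pi)


def gdd(phase_rad: np.ndarray, freqs_ghz: np.ndarray) -> np.ndarray:
    """Group delay distortion: tau(f) minus its band mean, per sweep.

    The phase must be unwrapped along frequency; steps at or near pi after
    the unwrap attempt (where unwrapping is ambiguous) trigger a warning
    but the computation proceeds.
    """
    ph = np.atleast_2d(np.asarray(phase_rad, dtype=float))
    ph = np.unwrap(ph, axis=-1)
    if np.any(np.abs(np.diff(ph, axis=-1)) >= np.pi - 1e-9):
        warnings.warn("phase jumps near pi remain after unwrapping; "
                      "group delay may be unreliable")
    tau = group_delay(ph, freqs_ghz)
    return tau - tau.mean(axis=-1, keepdims=True)


def peraf(curve: np.ndarray) -> np.ndarray:
    """Percent amplitude of fluctuation of each sweep's band curve.

    100 * mean(|x - mu|) / |mu| with mu the band mean; sweeps with mu = 0
    are undefined and masked as NaN.
    """
    y = np.atleast_2d(np.asarray(curve, dtype=float))
    mu = y.mean(axis=-1)
    dev = np.abs(y - mu[..., None]).mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * dev / np.abs(mu)
    out = np.where(mu == 0, np.nan, out)
    if np.any(mu == 0):
        warnings.warn("PerAF undefined (zero band mean) for some sweeps")
    return out


def _moving_time_auc(series: np.ndarray, times_s: np.ndarray,
                     window: int = 5) -> np.ndarray:
    """Trapezoidal integral of a per-sweep series over a centred sweep window."""
    n = len(series)
    half = window // 2
    out = np.empty(n)
    for k in range(n):
        a, b = max(0, k - half), min(n, k + half + 1)
        out[k] = np.trapezoid(series[a:b], times_s[a:b])
    return out


def extract_features(trial: ProcessedTrial, baseline_count: int = 5,
                     mdm_window: int = 5) -> dict[str, dict[str, np.ndarray]]:
    """All twelve per-sweep feature series of one processed trial.

    Returns ``{class_id: {"value": series, "location": series-or-None}}``.
    The MDM baseline prefers the quiescent pre-onset sweeps retained by the
    time-limiting step, falling back to the first ``baseline_count``
    processed sweeps.
    """
    f = trial.freqs_ghz
    ch = trial.channels
    n = trial.n_sweeps
    times = np.arange(n) / 1.0  # uniform sweep index axis

    mins = {}
    locs = {}
    for cid, name in (("a", "sxx_mag"), ("b", "sxy_mag")):
        idx = np.argmin(ch[name], axis=1)
        mins[cid] = ch[name][np.arange(n), idx]
        locs[cid] = f[idx]

    if trial.pre_onset is not None and len(trial.pre_onset["sxx_mag"]) > 0:
        base = (trial.pre_onset["sxx_mag"][:baseline_count],
                trial.pre_onset["sxy_mag"][:baseline_count])
        mdm = mdm_d(ch["sxx_mag"], ch["sxy_mag"], baseline=base)
    else:
        mdm = mdm_d(ch["sxx_mag"], ch["sxy_mag"],
                    baseline_count=baseline_count)
    rms = mdm_rms(mdm)

    out = {
        "a": {"value": mins["a"], "location": locs["a"]},
        "b": {"value": mins["b"], "location": locs["b"]},
        "c": {"value": auc(ch["sxx_mag"], f), "location": None},
        "d": {"value": auc(ch["sxy_mag"], f), "location": None},
        "e": {"value": auc(np.abs(gdd(ch["sxx_phase"], f)), f),
              "location": None},
        "f": {"value": auc(np.abs(gdd(ch["sxy_phase"], f)), f),
              "location": None},
        "g": {"value": auc(mdm, f), "location": None},
        "h": {"value": _moving_time_auc(rms, times, mdm_window),
              "location": None},
        "i": {"value": peraf(ch["sxx_mag"]), "location": None},
        "j": {"value": peraf(ch["sxy_mag"]), "location": None},
        "k": {"value": peraf(ch["sxx_phase"]), "location": None},
        "l": {"value": peraf(ch["sxy_phase"]), "location": None},
    }
    return out


def extract_feature_table(trial: ProcessedTrial,
                          variants: list[DatasetVariant] | None = None,
                          baseline_count: int = 5) -> pd.DataFrame:
    """Tidy per-sweep feature table of one trial across its variants.

    One row per (variant, class, sweep); a feature record in the catalog
    sense is one (trial, variant, class) series, so each variant
    contributes exactly twelve records.
    """
    if variants is None:
        variants = create_variants(trial)
    series = extract_features(trial, baseline_count=baseline_count)
    rows = []
    for var in variants:
        sl = var.slice
        sweep_idx = np.arange(var.start, var.stop + 1)
        pressure = var.pressure()
        for cid, payload in series.items():
            level, channel = FEATURE_CLASSES[cid]
            vals = payload["value"][sl]
            loc = payload["location"]
            locvals = loc[sl] if loc is not None else np.full(len(vals), np.nan)
            rows.append(pd.DataFrame({
                "sensor": trial.sensor_id,
                "trial": trial.trial_index,
                "placement": trial.placement,
                "variant": var.name,
                "class": cid,
                "level": level,
                "channel": channel,
                "sweep_index": sweep_idx,
                "value": vals,
                "location_GHz": locvals,
                "p_mmHg": pressure,
            }))
    return pd.concat(rows, ignore_index=True)
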