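"""On-disk interchange and reference-stream alignment.

Sweeps are stored as standard two-port Touchstone ``.s2p`` files (one per
sweep), the invasive reference stream as a CSV with header
``time_s,p_mmhg,t_C``, and a YAML manifest ties them together with the
trigger log. Touchstone dB/angle and real/imaginary dialects are accepted
on read; writing always uses dB/angle in GHz. Phases are wrapped on disk
and unwrapped along frequency on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    AlignedTrial,
    FormatError,
    FrequencyGrid,
    PressureTrajectory,
    SweepFrame,
    SynchronizationError,
    TrialRecord,
)

__all__ = [
    "write_trial",
    "read_trial",
    "align_reference",
    "write_touchstone",
    "read_touchstone",
    "window_means",
]

_MANIFEST_NAME = "manifest.yaml"
_REFERENCE_NAME = "reference.csv"


def write_touchstone(path: Path, freqs_ghz: np.ndarray,
                     frame: SweepFrame) -> None:
    """Write one sweep as a 2-port Touchstone file (dB/angle, GHz, 50 ohm).

    The reciprocal, symmetric two-port convention is used: S12 = S21 and
    S22 = S11, so the two measured channels fill the full matrix.
    """
    xx_deg = np.degrees(_wrap(frame.sxx_phase_rad))
    xy_deg = np.degrees(_wrap(frame.sxy_phase_rad))
    with open(path, "w") as fh:
        fh.write(f"! sweep at t={frame.time_s:.6f} s\n")
        fh.write("# GHZ S DB R 50\n")
        for i, f in enumerate(freqs_ghz):
            row = (f, frame.sxx_mag_db[i], xx_deg[i],
                   frame.sxy_mag_db[i], xy_deg[i],
                   frame.sxy_mag_db[i], xy_deg[i],
                   frame.sxx_mag_db[i], xx_deg[i])
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def _wrap(phase_rad: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * phase_rad))


_FREQ_SCALE = {"HZ": 1e-9, "KHZ": 1e-6, "MHZ": 1e-3, "GHZ": 1.0}


def read_touchstone(path: Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Parse a 2-port Touchstone file into frequency (GHz) and S11/S21 curves.

    Returns magnitudes in dB and phases in radians, unwrapped along
    frequency. Raises :class:`FormatError` with the offending line number on
    malformed input.
    """
    freq_scale = 1.0
    fmt = "DB"
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line[1:].upper().split()
                for tok in tokens:
                    if tok in _FREQ_SCALE:
                        freq_scale = _FREQ_SCALE[tok]
                    elif tok in ("DB", "MA", "RI"):
                        fmt = tok
                continue
            try:
                values = [float(v) for v in line.split()]
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: not numeric: {exc}") from exc
            if len(values) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 columns for a "
                    f"2-port record, got {len(values)}")
            rows.append(values)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.asarray(rows)
    freqs = data[:, 0] * freq_scale

    def to_db_rad(a: np.ndarray, b: np.ndarray):
        if fmt == "DB":
            return a, np.unwrap(np.radians(b))
        if fmt == "MA":
            return 20.0 * np.log10(a), np.unwrap(np.radians(b))
        z = a + 1j * b  # RI
        return 20.0 * np.log10(np.abs(z)), np.unwrap(np.angle(z))

    s11_mag, s11_ph = to_db_rad(data[:, 1], data[:, 2])
    s21_mag, s21_ph = to_db_rad(data[:, 3], data[:, 4])
    return freqs, {
        "sxx_mag": s11_mag, "sxx_phase": s11_ph,
        "sxy_mag": s21_mag, "sxy_phase": s21_ph,
    }


def write_trial(trial: TrialRecord, directory: Path | str) -> Path:
    """Serialize a trial: one ``.s2p`` per sweep, reference CSV, manifest.

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    freqs = trial.grid.frequencies_ghz
    sweep_files = []
    for k, frame in enumerate(trial.frames):
        name = f"sweep_{k:05d}.s2p"
        write_touchstone(directory / name, freqs, frame)
        sweep_files.append(name)

    ref = trial.reference
    pd.DataFrame({
        "time_s": ref.times_s,
        "p_mmHg": ref.p_mmhg,
        "t_C": ref.t_celsius,
    }).to_csv(directory / _REFERENCE_NAME, index=False)

    manifest = {
        "sensor_id": trial.sensor_id,
        "trial_index": trial.trial_index,
        "placement": trial.placement,
        "sweep_rate_hz": trial.sweep_rate_hz,
        "grid": {
            "f_start_ghz": trial.grid.f_start_ghz,
            "f_stop_ghz": trial.grid.f_stop_ghz,
            "n_points": trial.grid.n_points,
        },
        "reference": {
            "file": _REFERENCE_NAME,
            "pulse_rate_bpm": ref.pulse_rate_bpm,
            "p_max_mmhg": ref.p_max_mmhg,
            "lead_s": ref.lead_s,
        },
        "sweeps": [
            {"index": k, "file": name, "time_s": float(frame.time_s)}
            for k, (name, frame) in enumerate(zip(sweep_files, trial.frames))
        ],
        "triggers": [
            {"sweep": int(k), "time_s": float(t)} for k, t in trial.triggers
        ],
    }
    manifest_path = directory / _MANIFEST_NAME
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_trial(manifest_path: Path | str) -> TrialRecord:
    """Reconstruct a :class:`TrialRecord` written by :func:`write_trial`.

    Validates that every sweep file exists and that all frames share the
    manifest's frequency grid.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    directory = manifest_path.parent
    grid = FrequencyGrid(**manifest["grid"])
    expected = grid.frequencies_ghz

    frames = []
    for entry in manifest["sweeps"]:
        path = directory / entry["file"]
        if not path.exists():
            raise FormatError(f"missing sweep file: {entry['file']}")
        freqs, curves = read_touchstone(path)
        if len(freqs) != grid.n_points or not np.allclose(
                freqs, expected, rtol=0, atol=1e-9):
            raise FormatError(
                f"{entry['file']}: frequency grid mismatch "
                f"({len(freqs)} points vs expected {grid.n_points})")
        frames.append(SweepFrame(
            time_s=float(entry["time_s"]),
            sxx_mag_db=curves["sxx_mag"],
            sxx_phase_rad=curves["sxx_phase"],
            sxy_mag_db=curves["sxy_mag"],
            sxy_phase_rad=curves["sxy_phase"],
        ))

    ref_df = pd.read_csv(directory / manifest["reference"]["file"])
    ref_meta = manifest["reference"]
    p = ref_df["p_mmHg"].to_numpy()
    reference = PressureTrajectory(
        times_s=ref_df["time_s"].to_numpy(),
        p_mmhg=p,
        t_celsius=ref_df["t_C"].to_numpy(),
        ramp_mmhg=np.maximum.accumulate(p),  # nondecreasing envelope proxy
        pulse_rate_bpm=ref_meta["pulse_rate_bpm"],
        p_max_mmhg=ref_meta["p_max_mmhg"],
        lead_s=ref_meta["lead_s"],
    )
    triggers = [(int(t["sweep"]), float(t["time_s"]))
                for t in manifest["triggers"]]
    return TrialRecord(
        sensor_id=manifest["sensor_id"],
        trial_index=int(manifest["trial_index"]),
        placement=manifest["placement"],
        grid=grid,
        frames=frames,
        reference=reference,
        triggers=triggers,
        sweep_rate_hz=float(manifest["sweep_rate_hz"]),
    )


def window_means(values: np.ndarray, times: np.ndarray,
                 centers: np.ndarray, width: float) -> np.ndarray:
    """Mean of ``values`` over windows ``[c - width/2, c + width/2]``.

    ``times`` must be sorted. Windows that contain no sample raise
    :class:`SynchronizationError`.
    """
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    lo = np.searchsorted(times, centers - width / 2.0 - 1e-12, side="left")
    hi = np.searchsorted(times, centers + width / 2.0 + 1e-12, side="right")
    if np.any(hi <= lo):
        k = int(np.argmax(hi <= lo))
        raise SynchronizationError(
            f"no reference samples in the window of sweep {k}")
    return np.array([values[a:b].mean() for a, b in zip(lo, hi)])


def align_reference(trial: TrialRecord) -> AlignedTrial:
    """Attach per-sweep reference pressure/temperature via the trigger log.

    Each sweep's value is the mean of the reference stream over the sweep's
    acquisition window (1/sweep_rate wide) centred at its trigger timestamp,
    which is robust to the pulsatile component riding on the ramp.
    """
    trigger_map = dict(trial.triggers)
    for k in range(len(trial.frames)):
        if k not in trigger_map:
            raise SynchronizationError(f"no trigger for frame {k}")
    centers = np.array([trigger_map[k] for k in range(len(trial.frames))])
    width = 1.0 / trial.sweep_rate_hz
    ref = trial.reference
    if ref.sample_rate_hz < trial.sweep_rate_hz:
        raise SynchronizationError(
            "reference must be sampled at least at the sweep rate")
    p = window_means(ref.p_mmhg, ref.times_s, centers, width)
    t = window_means(ref.t_celsius, ref.times_s, centers, width)
    return AlignedTrial(trial=trial, p_at_sweep=p, t_at_sweep=t)
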