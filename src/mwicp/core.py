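"""Core containers shared across the pipeline.

Frequencies are handled in GHz, magnitudes in dB, phases in radians
(unwrapped along frequency inside the package, wrapped only on file
export), pressures in mmHg and times in seconds since trial start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PLACEMENTS = ("5mm", "10mm", "20mm", "30mm", "opposite")
SENSOR_IDS = ("A", "B", "C", "D", "E", "F")


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


class DegenerateInputError(ValueError):
    """Raised when an operation is undefined for the given input."""


class SynchronizationError(ValueError):
    """Raised when sweeps and the reference stream cannot be aligned."""


class FormatError(ValueError):
    """Raised for malformed or inconsistent on-disk recordings."""


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform frequency grid of a calibrated sweep.

    Defaults to the 2-6 GHz / 2001-point instrument grid (2 MHz spacing).
    """

    f_start_ghz: float = 2.0
    f_stop_ghz: float = 6.0
    n_points: int = 2001

    def __post_init__(self) -> None:
        if not self.f_start_ghz < self.f_stop_ghz:
            raise InvalidConfigError("f_start must be below f_stop")
        if self.n_points < 2:
            raise InvalidConfigError("grid needs at least 2 points")

    @property
    def frequencies_ghz(self) -> np.ndarray:
        return np.linspace(self.f_start_ghz, self.f_stop_ghz, self.n_points)

    @property
    def spacing_ghz(self) -> float:
        return (self.f_stop_ghz - self.f_start_ghz) / (self.n_points - 1)

    def contains(self, f_ghz: float) -> bool:
        return self.f_start_ghz <= f_ghz <= self.f_stop_ghz


@dataclass
class SweepFrame:
    """One two-port sweep: |S_XX|, |S_XY| in dB and their phases in rad."""

    time_s: float
    sxx_mag_db: np.ndarray
    sxx_phase_rad: np.ndarray
    sxy_mag_db: np.ndarray
    sxy_phase_rad: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sxx_mag_db)
        for arr in (self.sxx_phase_rad, self.sxy_mag_db, self.sxy_phase_rad):
            if len(arr) != n:
                raise FormatError("all four curves must share one grid")
        if self.time_s < 0:
            raise FormatError("frame time must be >= 0")


@dataclass
class PressureTrajectory:
    """Invasive reference stream: pressure/temperature sampled at a fixed rate.

    ``ramp_mmhg`` holds the nondecreasing pump component alone; ``p_mmhg`` is
    ramp plus the zero-mean pulsatile component.
    """

    times_s: np.ndarray
    p_mmhg: np.ndarray
    t_celsius: np.ndarray
    ramp_mmhg: np.ndarray
    pulse_rate_bpm: float
    p_max_mmhg: float
    lead_s: float

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(self.times_s[1] - self.times_s[0])


# channel keys used throughout the pipeline, in fixed order
CHANNELS = ("sxx_mag", "sxy_mag", "sxx_phase", "sxy_phase")


@dataclass
class TrialRecord:
    """One measurement trial of one sensor in one placement."""

    sensor_id: str
    trial_index: int
    placement: str
    grid: FrequencyGrid
    frames: list[SweepFrame]
    reference: PressureTrajectory
    triggers: list[tuple[int, float]]
    sweep_rate_hz: float = 3.0

    def __post_init__(self) -> None:
        if self.sensor_id not in SENSOR_IDS:
            raise InvalidConfigError(f"unknown sensor {self.sensor_id!r}")
        if self.placement not in PLACEMENTS:
            raise InvalidConfigError(f"unknown placement {self.placement!r}")
        times = [f.time_s for f in self.frames]
        if times != sorted(times):
            raise FormatError("frames must be sorted by time")

    def channel(self, name: str) -> np.ndarray:
        """Stack one channel across sweeps into an (n_sweeps, n_points) array."""
        attr = {
            "sxx_mag": "sxx_mag_db",
            "sxy_mag": "sxy_mag_db",
            "sxx_phase": "sxx_phase_rad",
            "sxy_phase": "sxy_phase_rad",
        }[name]
        return np.stack([getattr(f, attr) for f in self.frames])


@dataclass
class AlignedTrial:
    """Trial with per-sweep reference pressure/temperature attached."""

    trial: TrialRecord
    p_at_sweep: np.ndarray
    t_at_sweep: np.ndarray

    def __post_init__(self) -> None:
        if len(self.p_at_sweep) != len(self.trial.frames):
            raise SynchronizationError(
                "p_at_sweep must have one value per frame"
            )
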