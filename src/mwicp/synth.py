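"""Forward simulator of pressure-coupled phantom measurement trials.

The lab setup it emulates: a liquid brain phantom inside a skull phantom is
inflated by a dosing pump beating at 60 bpm until the intracranial pressure
reaches 60 mmHg, while a two-port VNA sweeps 2-6 GHz (2001 points) at 3 Hz
and an invasive pressure/temperature sensor samples at 5 kHz. Rising
pressure changes the effective dielectric load seen by the antennas, which
the simulator expresses as three couplings applied to a sensor-specific
baseline response: an amplitude offset concentrated around the resonance, a
resonance-frequency shift, and a phase offset.

Coupling magnitudes are synthetic defaults (no quantitative coefficients
exist for the physical setup); they are chosen so that the planted
pressure dependence dominates the instrument trace noise of 5e-3 dB RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    SENSOR_IDS,
    FrequencyGrid,
    InvalidConfigError,
    PressureTrajectory,
    SweepFrame,
    TrialRecord,
)

__all__ = [
    "SensorProfile",
    "CouplingModel",
    "SimulationConfig",
    "make_pressure_trajectory",
    "make_sensor_profile",
    "simulate_trial",
]


def _lorentzian_dip(f, f0, depth_db, width_ghz):
    x = (f - f0) / width_ghz
    return -depth_db / (1.0 + x * x)


@dataclass(frozen=True)
class SensorProfile:
    """Parametric baseline response of one sensor pair on the phantom.

    Magnitude curves are a flat matching level plus Lorentzian resonance
    dips; phase curves are a linear electrical delay plus an arctangent
    signature at the reflection resonance. The parametric form allows exact
    evaluation at shifted frequencies, which is how the pressure-driven
    resonance shift is applied.
    """

    sensor_id: str
    resonance_f0_ghz: float
    sxx_base_db: float
    sxx_dips: tuple[tuple[float, float, float], ...]  # (f0, depth, width)
    sxy_base_db: float
    sxy_dips: tuple[tuple[float, float, float], ...]
    delay_ns: float = 1.2
    phase_swing_rad: float = -2.0

    def sxx_mag_db(self, f_ghz: np.ndarray) -> np.ndarray:
        out = np.full_like(f_ghz, self.sxx_base_db, dtype=float)
        for f0, depth, width in self.sxx_dips:
            out += _lorentzian_dip(f_ghz, f0, depth, width)
        return out

    def sxy_mag_db(self, f_ghz: np.ndarray) -> np.ndarray:
        out = np.full_like(f_ghz, self.sxy_base_db, dtype=float)
        for f0, depth, width in self.sxy_dips:
            out += _lorentzian_dip(f_ghz, f0, depth, width)
        return out

    def sxx_phase_rad(self, f_ghz: np.ndarray) -> np.ndarray:
        # GHz * ns = dimensionless turns
        out = -2.0 * np.pi * f_ghz * self.delay_ns
        f0, _, width = self.sxx_dips[0]
        out += self.phase_swing_rad * np.arctan((f_ghz - f0) / width)
        return out

    def sxy_phase_rad(self, f_ghz: np.ndarray) -> np.ndarray:
        return -2.0 * np.pi * f_ghz * self.delay_ns * 1.5

    def baseline(self, grid: FrequencyGrid) -> dict[str, np.ndarray]:
        f = grid.frequencies_ghz
        return {
            "sxx_mag": self.sxx_mag_db(f),
            "sxy_mag": self.sxy_mag_db(f),
            "sxx_phase": self.sxx_phase_rad(f),
            "sxy_phase": self.sxy_phase_rad(f),
        }


# Printed baseline landmarks: (f0 GHz, dip depth target dB, width GHz).
# Depths are expressed as dip depth below the flat base level so the curve
# minimum lands exactly on the printed value.
_SENSOR_TABLE: dict[str, dict] = {
    # sharp S_XX dip of -35.3 dB at 3.565 GHz; S_XY -31.84 dB there
    "A": dict(f0=3.565, sxx_base=-7.5, sxx_min=-35.3, sxx_w=0.05,
              sxy_base=-30.0, sxy_dips=((3.565, 1.84, 0.08),)),
    # wide S_XX response, -25.31 dB at 3.658; sharp S_XY dip -65.87 at 3.604
    "B": dict(f0=3.658, sxx_base=-9.0, sxx_min=-25.31, sxx_w=0.5,
              sxy_base=-35.0, sxy_dips=((3.604, 30.87, 0.03),)),
    # relatively flat S_XX with a shallow dip at 2.886 GHz
    "C": dict(f0=2.886, sxx_base=-8.0, sxx_min=-15.0, sxx_w=0.3,
              sxy_base=-38.0, sxy_dips=()),
    # S_XX resonance at 3.21 GHz (-22.83 dB); stable S_XY near -35 dB
    "D": dict(f0=3.21, sxx_base=-7.0, sxx_min=-22.83, sxx_w=0.4,
              sxy_base=-35.0, sxy_dips=()),
    # S_XX resonance around 3.8 GHz (-20 dB); S_XY near -40 dB
    "E": dict(f0=3.8, sxx_base=-7.0, sxx_min=-20.0, sxx_w=0.3,
              sxy_base=-40.0, sxy_dips=()),
    # wideband S_XX with -35 dB at 4.4 GHz; S_XY near -30 dB
    "F": dict(f0=4.4, sxx_base=-8.0, sxx_min=-35.0, sxx_w=0.25,
              sxy_base=-30.0, sxy_dips=()),
}


def make_sensor_profile(sensor_id: str) -> SensorProfile:
    """Build the baseline profile of one of the six sensors (A..F).

    The reflection-magnitude minimum of the returned profile matches the
    documented resonance location and depth of that sensor on the phantom.
    """
    if sensor_id not in SENSOR_IDS:
        raise InvalidConfigError(f"unknown sensor {sensor_id!r}")
    t = _SENSOR_TABLE[sensor_id]
    return SensorProfile(
        sensor_id=sensor_id,
        resonance_f0_ghz=t["f0"],
        sxx_base_db=t["sxx_base"],
        sxx_dips=((t["f0"], t["sxx_base"] - t["sxx_min"], t["sxx_w"]),),
        sxy_base_db=t["sxy_base"],
        sxy_dips=t["sxy_dips"],
    )


@dataclass(frozen=True)
class CouplingModel:
    """Linear pressure-to-S-parameter coupling.

    alpha_mag_db_per_mmhg : amplitude offset at the resonance, applied with a
        Gaussian spectral shape (``shape_sigma_ghz``) centred on the
        resonance so the information concentrates in the optimal band.
    beta_freq_mhz_per_mmhg : resonance shift; the baseline is re-evaluated at
        shifted frequencies.
    gamma_phase_rad_per_mmhg : flat phase offset.
    """

    alpha_mag_db_per_mmhg: float = -0.05
    beta_freq_mhz_per_mmhg: float = 0.05
    gamma_phase_rad_per_mmhg: float = 0.003
    shape_sigma_ghz: float = 0.05
    applies_to: tuple[str, ...] = ("sxx", "sxy")

    def shape(self, f_ghz: np.ndarray, f0_ghz: float) -> np.ndarray:
        x = (f_ghz - f0_ghz) / self.shape_sigma_ghz
        return np.exp(-0.5 * x * x)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one trial bit-for-bit."""

    sensor_id: str = "A"
    trial_index: int = 1
    placement: str = "20mm"
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)
    coupling: CouplingModel = field(default_factory=CouplingModel)
    duration_s: float = 120.0
    lead_s: float = 5.0
    sweep_rate_hz: float = 3.0
    ref_rate_hz: float = 5000.0
    pulse_rate_bpm: float = 60.0
    pulse_amplitude_mmhg: float = 2.0
    p_max_mmhg: float = 60.0
    temperature_c: float = 23.0
    trace_noise_db: float = 5e-3
    trace_noise_phase_rad: float = 1e-3
    ramp_curvature: float = 0.15
    lead_jitter_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidConfigError("duration must be positive")
        if self.sweep_rate_hz <= 0 or self.ref_rate_hz <= 0:
            raise InvalidConfigError("rates must be positive")
        if self.pulse_rate_bpm <= 0:
            raise InvalidConfigError("pulse rate must be positive")
        if self.p_max_mmhg <= 0:
            raise InvalidConfigError("p_max must be positive")
        if not 0 <= self.lead_s < self.duration_s:
            raise InvalidConfigError("lead segment must fit in the trial")


def make_pressure_trajectory(config: SimulationConfig) -> PressureTrajectory:
    """Simulate the invasive reference stream of one pump ramp.

    A flat pre-pump lead segment at 0 mmHg is followed by a monotone ramp
    to ``p_max_mmhg`` with a superimposed zero-mean raised-cosine pulsation
    at the pump rate. The pulsation has zero mean over every full beat, so
    beat averages recover the ramp (exactly so for a linear ramp).

    Repeated physical trials never produce identical pressure courses, so
    two seeded jitters differentiate trials: the ramp follows a power law
    ``x**gamma`` with ``log gamma`` uniform in ``+-ramp_curvature`` (still
    monotone from 0 to p_max), and the pump start shifts uniformly within
    ``lead_jitter_s``. Both default to mild values and can be zeroed for
    an exactly linear, exactly timed ramp.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    gamma = float(np.exp(rng.uniform(-1.0, 1.0) * c.ramp_curvature))
    lead = c.lead_s + float(rng.uniform(0.0, c.lead_jitter_s))
    lead = min(lead, 0.9 * c.duration_s)
    # endpoint sample included so the ramp attains p_max exactly
    n = int(round(c.duration_s * c.ref_rate_hz)) + 1
    t = np.arange(n) / c.ref_rate_hz
    ramp_duration = c.duration_s - lead
    x = np.clip((t - lead) / ramp_duration, 0.0, 1.0)
    ramp = np.power(x, gamma) * c.p_max_mmhg
    # zero-mean per-beat pulsation, active only while the pump runs
    beat_hz = c.pulse_rate_bpm / 60.0
    tau = (t - lead) * beat_hz
    pulse = -0.5 * c.pulse_amplitude_mmhg * np.cos(2.0 * np.pi * tau)
    pulse[t < lead] = 0.0
    p = ramp + pulse
    temp = np.full(n, c.temperature_c)
    return PressureTrajectory(
        times_s=t,
        p_mmhg=p,
        t_celsius=temp,
        ramp_mmhg=ramp,
        pulse_rate_bpm=c.pulse_rate_bpm,
        p_max_mmhg=c.p_max_mmhg,
        lead_s=lead,
    )


def simulate_trial(config: SimulationConfig) -> TrialRecord:
    """Forward-simulate one trial: sweeps, reference stream and triggers.

    At each sweep the effective pressure is the reference pressure averaged
    over the sweep's acquisition window (the VNA integrates over its sweep
    interval); the baseline response is shifted in frequency by
    ``beta * p``, offset in magnitude by ``alpha * p * shape(f)`` and in
    phase by ``gamma * p``, then Gaussian trace noise is added.
    """
    c = config
    profile = make_sensor_profile(c.sensor_id)
    trajectory = make_pressure_trajectory(c)
    grid = c.grid
    f = grid.frequencies_ghz

    shift_max = c.coupling.beta_freq_mhz_per_mmhg * 1e-3 * c.p_max_mmhg
    if not grid.contains(profile.resonance_f0_ghz + shift_max) or \
            not grid.contains(profile.resonance_f0_ghz - abs(shift_max)):
        raise InvalidConfigError(
            "coupling shifts the resonance outside the frequency grid")

    n_sweeps = int(np.floor(c.duration_s * c.sweep_rate_hz))
    dt = 1.0 / c.sweep_rate_hz
    start_times = np.arange(n_sweeps) * dt
    trigger_times = start_times + dt / 2.0

    # effective pressure per sweep: mean over the acquisition window
    from .io_sync import window_means

    p_eff = window_means(
        trajectory.p_mmhg, trajectory.times_s, trigger_times, dt)

    rng = np.random.default_rng(c.seed)
    shape = c.coupling.shape(f, profile.resonance_f0_ghz)
    frames = []
    for k in range(n_sweeps):
        p = p_eff[k]
        df = c.coupling.beta_freq_mhz_per_mmhg * 1e-3 * p
        bump = c.coupling.alpha_mag_db_per_mmhg * p * shape
        gphase = c.coupling.gamma_phase_rad_per_mmhg * p

        sxx_mag = profile.sxx_mag_db(f - df)
        sxy_mag = profile.sxy_mag_db(f - df)
        sxx_phase = profile.sxx_phase_rad(f - df)
        sxy_phase = profile.sxy_phase_rad(f - df)
        if "sxx" in c.coupling.applies_to:
            sxx_mag = sxx_mag + bump
            sxx_phase = sxx_phase + gphase
        if "sxy" in c.coupling.applies_to:
            sxy_mag = sxy_mag + bump
            sxy_phase = sxy_phase + gphase
        if c.trace_noise_db > 0:
            sxx_mag = sxx_mag + rng.normal(0.0, c.trace_noise_db, f.shape)
            sxy_mag = sxy_mag + rng.normal(0.0, c.trace_noise_db, f.shape)
        if c.trace_noise_phase_rad > 0:
            sxx_phase = sxx_phase + rng.normal(
                0.0, c.trace_noise_phase_rad, f.shape)
            sxy_phase = sxy_phase + rng.normal(
                0.0, c.trace_noise_phase_rad, f.shape)
        frames.append(SweepFrame(
            time_s=float(start_times[k]),
            sxx_mag_db=sxx_mag,
            sxx_phase_rad=sxx_phase,
            sxy_mag_db=sxy_mag,
            sxy_phase_rad=sxy_phase,
        ))

    triggers = [(k, float(trigger_times[k])) for k in range(n_sweeps)]
    return TrialRecord(
        sensor_id=c.sensor_id,
        trial_index=c.trial_index,
        placement=c.placement,
        grid=grid,
        frames=frames,
        reference=trajectory,
        triggers=triggers,
        sweep_rate_hz=c.sweep_rate_hz,
    )
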