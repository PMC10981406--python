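"""Synthetic cohorts of animals with cardiac-gated pulsatile perivascular flow.

This module generates the ground-truth physiology that the imaging forward
model (:mod:`pvspulse.dwi_forward`) and the ultrasound arm consume: per-animal
cardiac timing, perivascular flow amplitude, carotid wall pulsation and noise
level, together with ECG event streams, M-mode diameter traces and Doppler
blood-velocity traces.

The central object is the *velocity envelope*: a raised-cosine pulse of width
``systolic_width`` centred ``arrival_delay`` ms after each R-wave, repeating
every cardiac period.  It models the systolic bolus of perivascular fluid
movement — forward motion driven by the arterial pulse wave, with essentially
no motion during diastole.  Everything cardiac-phase-dependent (directional
PVS flow, isotropic CSF dispersion in control regions, vessel-wall distension,
the Doppler velocity pulse) is synchronised to this envelope.

Two named presets are provided:

``multidelay``
    the 10-animal multi-ECG-delay study: heart rate 364 bpm, pulse arrival
    25 ms after the R-wave, flow amplitude calibrated so the noise-free
    directionality index ΔD* at the systolic gate is 0.004 mm²/s.
``hypertension``
    the angiotensin-II (Ang-II) vs vehicle study (n = 6 per group): identical
    timing, but the flow amplitude is calibrated per group to the baseline
    cohort summaries (0.005 mm²/s for the Ang-II group, 0.004 for vehicle).

Between-animal variability is log-normal (multiplicative, positivity-
preserving) on the flow amplitude and the wall-pulsation amplitude; all other
randomness is measurement noise.  Every stochastic function takes an explicit
seed and all cohort-level seeds are spawned hierarchically from the master
seed, so experiments are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CardiacCycleParams",
    "FlowParams",
    "WallParams",
    "AnimalParams",
    "CohortConfig",
    "ConditionEffect",
    "MModeTrace",
    "DopplerTrace",
    "velocity_envelope",
    "draw_cohort",
    "apply_condition",
    "condition_effect",
    "simulate_ecg",
    "simulate_mmode",
    "simulate_doppler",
    "preset_animal",
    "save_trace",
    "load_trace",
    "PRESET_NAMES",
]

# ---------------------------------------------------------------------------
# Generator constants (study conditions)
# ---------------------------------------------------------------------------

#: baseline / post-Ang-II heart rates, beats per minute
BASELINE_HEART_RATE = 364.0
ANG2_HEART_RATE = 353.0

#: R-wave -> arrival of the pulse wave at the MCA perivascular space, ms
DEFAULT_ARRIVAL_DELAY = 25.0
#: duration of the systolic velocity pulse, ms
DEFAULT_SYSTOLIC_WIDTH = 50.0

#: carotid wall-motion amplitudes (systolic - diastolic diameter), mm
BASELINE_WALL_MOTION = 0.22
ANG2_WALL_MOTION = 0.17
#: diastolic common-carotid diameter of an adult rat, mm
DEFAULT_DIASTOLIC_DIAMETER = 1.0

#: R-wave -> peak carotid blood velocity, ms (baseline / post-Ang-II)
BASELINE_PEAK_VELOCITY_OFFSET = 40.64
ANG2_TIMING_SHIFT = 40.36 - 40.64

#: directionality targets used to calibrate flow amplitude, mm^2/s
MULTIDELAY_DELTA_DSTAR = 0.004
ANG2_BASELINE_DELTA_DSTAR = 0.005
ANG2_POST_DELTA_DSTAR = 0.003
VEHICLE_DELTA_DSTAR = 0.004

#: isotropic pseudo-diffusivity of perivascular fluid, mm^2/s
DEFAULT_D_FREE = 0.002
#: fraction of the pulsatile dispersion that acts isotropically
DEFAULT_PERP_PULSATILE_GAIN = 0.3

DEFAULT_SNR = 40.0
DEFAULT_BETWEEN_ANIMAL_CV = 0.2
#: between-animal CV of wall pulsation, from the 0.22 ± 0.02 mm cohort summary
WALL_MOTION_CV = 0.02 / BASELINE_WALL_MOTION

#: M-mode additive noise, as a fraction of the wall-pulsation amplitude
MMODE_NOISE_FRACTION = 0.01
#: peak systolic carotid blood velocity used for Doppler traces, mm/s
DOPPLER_PEAK_VELOCITY = 500.0
#: diastolic floor of the Doppler velocity trace, as a fraction of the peak
DOPPLER_DIASTOLIC_FRACTION = 0.15
#: Doppler additive noise, fraction of the peak velocity
DOPPLER_NOISE_FRACTION = 0.01

MMODE_SAMPLING_HZ = 1000.0
DOPPLER_SAMPLING_HZ = 10000.0

PRESET_NAMES = ("multidelay", "hypertension")
CONDITIONS = ("baseline", "ang2", "vehicle")

FLOW_PROFILES = ("uniform", "plug", "parabolic")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CardiacCycleParams:
    """Cardiac timing: rate, pulse arrival delay and systolic pulse width (ms)."""

    heart_rate: float
    arrival_delay: float = DEFAULT_ARRIVAL_DELAY
    systolic_width: float = DEFAULT_SYSTOLIC_WIDTH

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if not 0 <= self.arrival_delay < self.period:
            raise ValueError("arrival_delay must lie in [0, period)")
        if not 0 < self.systolic_width < self.period:
            raise ValueError("systolic_width must lie in (0, period)")

    @property
    def period(self) -> float:
        """Cardiac period in ms (60000 / heart_rate)."""
        return 60000.0 / self.heart_rate


@dataclass(frozen=True)
class FlowParams:
    """Perivascular fluid-movement parameters.

    ``v_peak`` is the upper bound of the within-voxel speed distribution at
    the systolic peak of the envelope (mm/s); ``profile`` sets the shape of
    that distribution; ``d_free`` is the isotropic pseudo-diffusivity of the
    fluid (mm²/s); ``perp_pulsatile_gain`` is the fraction of the pulsatile
    dispersion that acts isotropically (giving the perpendicular direction its
    cardiac dependence).
    """

    v_peak: float
    profile: str = "uniform"
    d_free: float = DEFAULT_D_FREE
    perp_pulsatile_gain: float = DEFAULT_PERP_PULSATILE_GAIN

    def __post_init__(self) -> None:
        if self.v_peak < 0:
            raise ValueError("v_peak must be non-negative")
        if self.d_free <= 0:
            raise ValueError("d_free must be positive")
        if not 0 <= self.perp_pulsatile_gain <= 1:
            raise ValueError("perp_pulsatile_gain must lie in [0, 1]")
        if self.profile not in FLOW_PROFILES:
            raise ValueError(f"unknown flow profile {self.profile!r}")


@dataclass(frozen=True)
class WallParams:
    """Carotid geometry/pulsation: diameters in mm, timing offset in ms."""

    diastolic_diameter: float = DEFAULT_DIASTOLIC_DIAMETER
    pulsation_amplitude: float = BASELINE_WALL_MOTION
    peak_velocity_offset: float = BASELINE_PEAK_VELOCITY_OFFSET

    def __post_init__(self) -> None:
        if self.diastolic_diameter <= 0:
            raise ValueError("diastolic_diameter must be positive")
        if self.pulsation_amplitude < 0:
            raise ValueError("pulsation_amplitude must be non-negative")
        if self.peak_velocity_offset < 0:
            raise ValueError("peak_velocity_offset must be non-negative")


@dataclass(frozen=True)
class AnimalParams:
    """One simulated subject."""

    id: str
    cycle: CardiacCycleParams
    flow: FlowParams
    wall: WallParams
    snr: float = DEFAULT_SNR

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.wall.peak_velocity_offset >= self.cycle.period:
            raise ValueError("peak_velocity_offset must be below the cardiac period")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sampling configuration.

    ``condition`` labels group membership ("baseline", "ang2", "vehicle");
    animals are always drawn in their *baseline* physiological state — the
    Ang-II post state is produced by :func:`apply_condition`.  For the
    ``hypertension`` preset the condition selects the group-specific baseline
    flow calibration.

    ``between_animal_cv`` applies to the flow amplitude ``v_peak``.  Wall
    pulsation has its own, smaller, between-animal CV (``wall_cv``; when
    ``None`` it defaults to the cohort value implied by the printed wall
    motion summary, 0.02/0.22 ≈ 0.09, capped at ``between_animal_cv`` so a
    zero-variance cohort is fully degenerate).
    """

    n_animals: int
    condition: str = "baseline"
    between_animal_cv: float = DEFAULT_BETWEEN_ANIMAL_CV
    seed: int = 0
    named_preset: str = "multidelay"
    wall_cv: float | None = None

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.between_animal_cv < 0:
            raise ValueError("between_animal_cv must be non-negative")
        if self.wall_cv is not None and self.wall_cv < 0:
            raise ValueError("wall_cv must be non-negative")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.named_preset not in PRESET_NAMES:
            raise ValueError(f"unknown preset {self.named_preset!r}")


@dataclass(frozen=True)
class ConditionEffect:
    """Static parameter scaling describing a pharmacological condition.

    Ang-II dampens wall pulsation (``wall_scale``) and perivascular flow
    (``v_scale``), slightly lowers the heart rate and shifts the R-wave to
    peak-velocity interval by ``timing_shift_ms``; the vehicle effect is the
    identity.
    """

    v_scale: float = 1.0
    wall_scale: float = 1.0
    heart_rate_post: float = BASELINE_HEART_RATE
    timing_shift_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.v_scale <= 1 or not 0 < self.wall_scale <= 1:
            raise ValueError("condition scales must lie in (0, 1]")
        if self.heart_rate_post <= 0:
            raise ValueError("heart_rate_post must be positive")


@dataclass(frozen=True)
class MModeTrace:
    """Vessel-diameter time series (mm) with the R-wave events that gate it."""

    times: np.ndarray
    diameters: np.ndarray
    r_wave_times: np.ndarray

    def __post_init__(self) -> None:
        _validate_trace(self.times, self.diameters)
        if np.any(np.asarray(self.diameters) <= 0):
            raise ValueError("diameters must be positive")


@dataclass(frozen=True)
class DopplerTrace:
    """Blood-velocity time series (mm/s) with R-wave events."""

    times: np.ndarray
    velocities: np.ndarray
    r_wave_times: np.ndarray

    def __post_init__(self) -> None:
        _validate_trace(self.times, self.velocities)


def _validate_trace(times: np.ndarray, values: np.ndarray) -> None:
    times = np.asarray(times)
    values = np.asarray(values)
    if times.shape != values.shape:
        raise ValueError("times and values must have equal length")
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")


# ---------------------------------------------------------------------------
# Velocity envelope
# ---------------------------------------------------------------------------

def velocity_envelope(t, cycle: CardiacCycleParams):
    """Normalised cardiac velocity envelope at time(s) ``t`` (ms after R-wave).

    A raised-cosine pulse of width ``cycle.systolic_width`` centred at
    ``cycle.arrival_delay``, repeated with the cardiac period: 1 at the
    systolic peak, exactly 0 outside the pulse.  Vectorised over ``t``.
    """
    t = np.asarray(t, dtype=float)
    period = cycle.period
    # signed distance from the nearest pulse centre, in [-period/2, period/2)
    x = (t - cycle.arrival_delay + period / 2.0) % period - period / 2.0
    half = cycle.systolic_width / 2.0
    env = np.where(np.abs(x) <= half,
                   0.5 * (1.0 + np.cos(np.pi * x / half)),
                   0.0)
    return env if env.ndim else float(env)


# ---------------------------------------------------------------------------
# Presets and conditions
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _calibrated_v_peak(target: float) -> float:
    # lazy import: dwi_forward depends on this module for the cardiac types.
    # Presets are calibrated at the cohort-expectation level: the printed
    # study values are cohort means, and the flow term is convex in v_peak.
    from .dwi_forward import PGSEParams, calibrate_cohort_v_peak

    return calibrate_cohort_v_peak(target, PGSEParams(),
                                   cv=DEFAULT_BETWEEN_ANIMAL_CV)


def _baseline_delta_dstar(preset: str, condition: str) -> float:
    if preset == "multidelay":
        return MULTIDELAY_DELTA_DSTAR
    if condition == "vehicle":
        return VEHICLE_DELTA_DSTAR
    return ANG2_BASELINE_DELTA_DSTAR


def preset_animal(preset: str, condition: str = "baseline",
                  animal_id: str = "template") -> AnimalParams:
    """Return the preset-mean (baseline-state) animal for a named preset."""
    if preset not in PRESET_NAMES:
        raise ValueError(f"unknown preset {preset!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    v_peak = _calibrated_v_peak(_baseline_delta_dstar(preset, condition))
    return AnimalParams(
        id=animal_id,
        cycle=CardiacCycleParams(heart_rate=BASELINE_HEART_RATE),
        flow=FlowParams(v_peak=v_peak),
        wall=WallParams(),
        snr=DEFAULT_SNR,
    )


def condition_effect(condition: str) -> ConditionEffect:
    """The parameter scaling for a named condition ("ang2" or "vehicle")."""
    if condition in ("vehicle", "baseline"):
        return ConditionEffect()
    if condition == "ang2":
        v_scale = (_calibrated_v_peak(ANG2_POST_DELTA_DSTAR)
                   / _calibrated_v_peak(ANG2_BASELINE_DELTA_DSTAR))
        return ConditionEffect(
            v_scale=v_scale,
            wall_scale=ANG2_WALL_MOTION / BASELINE_WALL_MOTION,
            heart_rate_post=ANG2_HEART_RATE,
            timing_shift_ms=ANG2_TIMING_SHIFT,
        )
    raise ValueError(f"unknown condition {condition!r}")


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def _lognormal_multipliers(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean log-normal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def draw_cohort(config: CohortConfig) -> list[AnimalParams]:
    """Draw ``config.n_animals`` subjects around the preset means.

    v_peak and pulsation_amplitude vary log-normally between animals with
    CV = ``between_animal_cv``; timing and noise parameters are shared.
    Deterministic given ``config.seed``.
    """
    template = preset_animal(config.named_preset, config.condition)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    wall_cv = config.wall_cv if config.wall_cv is not None \
        else min(config.between_animal_cv, WALL_MOTION_CV)
    v_mult = _lognormal_multipliers(rng, config.between_animal_cv, config.n_animals)
    w_mult = _lognormal_multipliers(rng, wall_cv, config.n_animals)
    cohort = []
    for i in range(config.n_animals):
        cohort.append(replace(
            template,
            id=f"{config.named_preset}-{config.condition}-{i + 1:02d}",
            flow=replace(template.flow, v_peak=template.flow.v_peak * v_mult[i]),
            wall=replace(template.wall,
                         pulsation_amplitude=template.wall.pulsation_amplitude * w_mult[i]),
        ))
    return cohort


def apply_condition(animal: AnimalParams, effect: ConditionEffect) -> AnimalParams:
    """Return a copy of ``animal`` with the condition scaling applied."""
    return replace(
        animal,
        cycle=replace(animal.cycle, heart_rate=effect.heart_rate_post),
        flow=replace(animal.flow, v_peak=animal.flow.v_peak * effect.v_scale),
        wall=replace(
            animal.wall,
            pulsation_amplitude=animal.wall.pulsation_amplitude * effect.wall_scale,
            peak_velocity_offset=animal.wall.peak_velocity_offset + effect.timing_shift_ms,
        ),
    )


# ---------------------------------------------------------------------------
# ECG / ultrasound trace simulation
# ---------------------------------------------------------------------------

def simulate_ecg(cycle: CardiacCycleParams, duration: float) -> np.ndarray:
    """R-wave event times (ms): evenly spaced at the cardiac period from 0.

    ``duration`` must exceed one period so at least two events exist.
    """
    if duration <= cycle.period:
        raise ValueError("duration must exceed one cardiac period")
    return np.arange(0.0, duration, cycle.period)


def simulate_mmode(animal: AnimalParams, duration: float, seed,
                   sampling_hz: float = MMODE_SAMPLING_HZ,
                   noise_fraction: float = MMODE_NOISE_FRACTION) -> MModeTrace:
    """Simulate an M-mode vessel-diameter trace.

    diameter(t) = diastolic_diameter + pulsation_amplitude * envelope(t)
    plus additive Gaussian noise with SD ``noise_fraction`` of the pulsation
    amplitude.  Requires at least 3 cardiac cycles.
    """
    times = _sample_times(animal, duration, sampling_hz)
    rng = np.random.default_rng(seed)
    env = velocity_envelope(times, animal.cycle)
    diameters = animal.wall.diastolic_diameter + animal.wall.pulsation_amplitude * env
    sd = noise_fraction * animal.wall.pulsation_amplitude
    if sd > 0:
        diameters = diameters + rng.normal(0.0, sd, size=times.size)
    return MModeTrace(times=times, diameters=diameters,
                      r_wave_times=simulate_ecg(animal.cycle, duration))


def simulate_doppler(animal: AnimalParams, duration: float, seed,
                     sampling_hz: float = DOPPLER_SAMPLING_HZ,
                     peak_velocity: float = DOPPLER_PEAK_VELOCITY,
                     noise_fraction: float = DOPPLER_NOISE_FRACTION) -> DopplerTrace:
    """Simulate a Doppler blood-velocity trace.

    A raised-cosine systolic pulse peaks ``peak_velocity_offset`` ms after
    each R-wave on top of a diastolic velocity floor, with additive Gaussian
    noise (SD ``noise_fraction`` of the peak velocity).
    """
    times = _sample_times(animal, duration, sampling_hz)
    rng = np.random.default_rng(seed)
    pulse_cycle = CardiacCycleParams(
        heart_rate=animal.cycle.heart_rate,
        arrival_delay=animal.wall.peak_velocity_offset,
        systolic_width=animal.cycle.systolic_width,
    )
    floor = DOPPLER_DIASTOLIC_FRACTION * peak_velocity
    velocities = floor + (peak_velocity - floor) * velocity_envelope(times, pulse_cycle)
    sd = noise_fraction * peak_velocity
    if sd > 0:
        velocities = velocities + rng.normal(0.0, sd, size=times.size)
    return DopplerTrace(times=times, velocities=velocities,
                        r_wave_times=simulate_ecg(animal.cycle, duration))


def _sample_times(animal: AnimalParams, duration: float, sampling_hz: float) -> np.ndarray:
    if duration < 3 * animal.cycle.period:
        raise ValueError("duration must cover at least 3 cardiac cycles")
    dt = 1000.0 / sampling_hz  # ms per sample
    return np.arange(0.0, duration, dt)


# ---------------------------------------------------------------------------
# Trace I/O: CSV (time_ms, value, channel) + JSON sidecar with R-wave times
# ---------------------------------------------------------------------------

def save_trace(trace: MModeTrace | DopplerTrace, path: str | Path) -> None:
    """Write a trace as CSV with an R-wave-times JSON sidecar next to it."""
    path = Path(path)
    if isinstance(trace, MModeTrace):
        channel, values = "mmode_diameter_mm", trace.diameters
    else:
        channel, values = "doppler_velocity_mm_per_s", trace.velocities
    pd.DataFrame({"time_ms": trace.times, "value": values,
                  "channel": channel}).to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"r_wave_times_ms": np.asarray(trace.r_wave_times).tolist()}, indent=1))


def load_trace(path: str | Path) -> MModeTrace | DopplerTrace:
    """Read a trace written by :func:`save_trace`."""
    path = Path(path)
    df = pd.read_csv(path)
    r_waves = np.asarray(
        json.loads(path.with_suffix(".json").read_text())["r_wave_times_ms"])
    channel = df["channel"].iloc[0]
    if channel == "mmode_diameter_mm":
        return MModeTrace(times=df["time_ms"].to_numpy(),
                          diameters=df["value"].to_numpy(), r_wave_times=r_waves)
    if channel == "doppler_velocity_mm_per_s":
        return DopplerTrace(times=df["time_ms"].to_numpy(),
                            velocities=df["value"].to_numpy(), r_wave_times=r_waves)
    raise ValueError(f"unknown trace channel {channel!r}")
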