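"""Forward model of the ECG-gated low b-value pulsed-gradient spin-echo scan.

The signal model has three ingredients:

1. **Spin-phase attenuation from pulsatile flow.**  A pulsed-gradient
   spin-echo (PGSE) pair (amplitude G, lobe duration δ, separation Δ) imparts
   a phase φ = γ·G·δ·Δ·v to a spin moving with constant velocity component v
   along the gradient axis.  Encoding is quasi-static: the per-spin velocity
   is held at its value at the gate time, ``v_eff = v_peak × envelope(delay)``
   (the 31 ms encoding window is short relative to the systolic pulse, and
   sampling the envelope at the gate keeps the measured delay-response peak at
   the pulse-arrival delay).  For a within-voxel speed distribution the
   magnitude signal is attenuated by |⟨e^{iφ}⟩|; for the default uniform
   distribution on [0, v_eff] this has the sinc-type closed form
   |sin(a/2)/(a/2)| with a = γGδΔ·v_eff, which serves as the analytic oracle
   for the Monte-Carlo path.

2. **Isotropic (pseudo-)diffusion.**  Gaussian attenuation exp(−b·D) with a
   compartment-specific D.  In the perivascular space a fraction
   ``perp_pulsatile_gain`` of the pulsatile dispersion acts isotropically, so
   the perpendicular direction inherits a cardiac dependence; in the
   subarachnoid space and third ventricle the pulsatile dispersion is entirely
   isotropic (cardiac-dependent but direction-independent); brain tissue has a
   fixed low ADC and a low S0 (the long-TE protocol suppresses tissue signal).

3. **Rician measurement noise** from two independent Gaussian channels, with
   SNR defined on the b0 perivascular signal.

The phantom places the right perivascular tract along the frequency-encoding
(FE, first in-plane) axis and the left tract along the phase-encoding (PE)
axis, so a gradient on FE is parallel to the right tract and perpendicular to
the left, and vice versa.

b-value note: the printed protocol value is 43 s/mm², while (γGδ)²(Δ−δ/3)
for the stated gradients evaluates to ≈39.2 s/mm² (imaging-gradient cross
terms presumably make up the difference).  The nominal 43 is used by default
for both the forward exponent and the inversion (self-consistent); pass
``use_nominal_b=False`` to use the computed value throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.optimize import brentq

from .synth_cohort import AnimalParams, CardiacCycleParams, FlowParams, velocity_envelope

__all__ = [
    "GAMMA_PROTON",
    "PGSEParams",
    "AcquisitionParams",
    "PhantomGeometry",
    "DWIVolume",
    "CompartmentSignalModel",
    "compute_b_value",
    "effective_b",
    "analytic_attenuation_uniform",
    "flow_dstar",
    "mc_attenuation",
    "calibrate_v_peak",
    "make_phantom",
    "render_volume",
    "add_rician_noise",
    "save_volume",
    "load_volume",
    "save_phantom",
    "load_phantom",
    "REGION_LABELS",
    "REGION_S0",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 2.6752218708e8

#: apparent diffusion coefficient of suppressed brain tissue, mm^2/s
TISSUE_ADC = 7.0e-4
#: isotropic pseudo-diffusivity of CSF in the control compartments, mm^2/s
CSF_D = 2.0e-3
#: peak pulsatile isotropic dispersion added in SAS / third ventricle, mm^2/s
SAS_PULSE_AMPLITUDE = 3.0e-3
VENTRICLE_PULSE_AMPLITUDE = 2.0e-3

#: relative b0 signal per region (long-TE contrast: CSF bright, tissue dark)
REGION_S0 = {
    "background": 0.0,
    "tissue": 0.1,
    "right_PVS": 1.0,
    "left_PVS": 1.0,
    "SAS": 1.0,
    "third_ventricle": 1.0,
}

REGION_LABELS = {
    "background": 0,
    "tissue": 1,
    "right_PVS": 2,
    "left_PVS": 3,
    "SAS": 4,
    "third_ventricle": 5,
}

MPG_AXES = ("FE", "PE", "none")


# ---------------------------------------------------------------------------
# PGSE parameters and b-value
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PGSEParams:
    """Motion-probing gradient pair: G in T/m, δ and Δ in ms.

    ``axis`` is the in-plane gradient direction ("FE", "PE") or "none" for the
    unweighted b0 acquisition.  ``b_nominal`` is the protocol's printed
    b-value in s/mm².
    """

    gradient_amplitude: float = 0.03
    delta: float = 5.0
    Delta: float = 26.0
    axis: str = "FE"
    gamma: float = GAMMA_PROTON
    b_nominal: float = 43.0

    def __post_init__(self) -> None:
        if self.gradient_amplitude < 0:
            raise ValueError("gradient_amplitude must be non-negative")
        if not self.delta < self.Delta:
            raise ValueError("delta must be smaller than Delta")
        if self.axis not in MPG_AXES:
            raise ValueError(f"unknown gradient axis {self.axis!r}")

    @property
    def phase_per_velocity(self) -> float:
        """Spin phase per unit velocity, rad/(mm/s): γ·G·δ·Δ in SI × 1e-3."""
        return self.gamma * self.gradient_amplitude * (self.delta * 1e-3) \
            * (self.Delta * 1e-3) * 1e-3


def compute_b_value(pgse: PGSEParams) -> float:
    """b = (γGδ)²(Δ − δ/3) for rectangular PGSE lobes, in s/mm².

    Returns 0 for the unweighted (axis="none") acquisition.
    """
    if pgse.axis == "none":
        return 0.0
    q = pgse.gamma * pgse.gradient_amplitude * pgse.delta * 1e-3  # rad/m
    b_si = q * q * (pgse.Delta - pgse.delta / 3.0) * 1e-3  # s/m^2
    return b_si * 1e-6  # s/mm^2


def effective_b(pgse: PGSEParams, use_nominal_b: bool = True) -> float:
    """The b-value used in exponents and inversion (0 for b0)."""
    if pgse.axis == "none":
        return 0.0
    return pgse.b_nominal if use_nominal_b else compute_b_value(pgse)


# ---------------------------------------------------------------------------
# Flow attenuation: analytic oracle, Monte Carlo, calibration
# ---------------------------------------------------------------------------

def analytic_attenuation_uniform(v_max: float, pgse: PGSEParams) -> float:
    """|sin(a/2)/(a/2)| with a = γGδΔ·v_max — closed-form magnitude
    attenuation for speeds uniform on [0, v_max] along the gradient axis."""
    if v_max < 0:
        raise ValueError("v_max must be non-negative")
    a = pgse.phase_per_velocity * v_max
    if a == 0:
        return 1.0
    return float(abs(np.sinc(a / (2.0 * np.pi))))  # np.sinc(x) = sin(pi x)/(pi x)


def flow_dstar(v_eff: float, pgse: PGSEParams, use_nominal_b: bool = True) -> float:
    """Pseudo-diffusion equivalent of the uniform-profile flow attenuation:
    −ln|sinc|/b, in mm²/s (0 when v_eff = 0)."""
    if v_eff == 0:
        return 0.0
    b = effective_b(pgse, use_nominal_b)
    return -np.log(analytic_attenuation_uniform(v_eff, pgse)) / b


def _draw_speeds(profile: str, v_eff: float, n_spins: int,
                 rng: np.random.Generator) -> np.ndarray:
    if profile == "uniform":
        return rng.uniform(0.0, v_eff, size=n_spins)
    if profile == "plug":
        return np.full(n_spins, v_eff)
    if profile == "parabolic":
        # radial positions sampled uniformly along a diameter
        r = rng.uniform(0.0, 1.0, size=n_spins)
        return v_eff * (1.0 - r * r)
    raise ValueError(f"unknown flow profile {profile!r}")


def mc_attenuation(flow: FlowParams, pgse: PGSEParams, ecg_delay: float,
                   cycle: CardiacCycleParams, alignment: str,
                   n_spins: int = 20000, seed=None,
                   use_nominal_b: bool = True) -> float:
    """Monte-Carlo magnitude attenuation of a perivascular compartment.

    Per-spin speeds are drawn from ``flow.profile`` scaled by the gate-time
    effective velocity ``v_eff = v_peak × envelope(ecg_delay)``; the spin
    phase is γGδΔ times the velocity component along the gradient axis (the
    full speed when ``alignment="parallel"``, zero when "perpendicular").
    The coherent-phase magnitude |⟨e^{iφ}⟩| is multiplied by Gaussian
    attenuation from the isotropic pseudo-diffusivity
    ``d_free + perp_pulsatile_gain × D_flow(v_eff)`` (the isotropic share of
    the pulsatile dispersion, which cancels in the parallel−perpendicular
    difference).  Deterministic given ``seed``.
    """
    if n_spins < 1000:
        raise ValueError("n_spins must be at least 1000")
    if alignment not in ("parallel", "perpendicular"):
        raise ValueError(f"unknown alignment {alignment!r}")
    rng = np.random.default_rng(seed)
    v_eff = flow.v_peak * velocity_envelope(ecg_delay, cycle)
    b = effective_b(pgse, use_nominal_b)
    if alignment == "parallel" and v_eff > 0:
        phases = pgse.phase_per_velocity * _draw_speeds(
            flow.profile, v_eff, n_spins, rng)
        coherence = float(abs(np.mean(np.exp(1j * phases))))
    else:
        coherence = 1.0
    d_iso = flow.d_free + flow.perp_pulsatile_gain * flow_dstar(
        v_eff, pgse, use_nominal_b)
    return coherence * float(np.exp(-b * d_iso))


def calibrate_v_peak(target_delta_dstar: float, pgse: PGSEParams,
                     cycle: CardiacCycleParams | None = None,
                     flow_template: FlowParams | None = None,
                     use_nominal_b: bool = True, tol: float = 1e-7) -> float:
    """Peak effective velocity (mm/s) whose noise-free directionality index
    ΔD* at the systolic gate equals ``target_delta_dstar`` (mm²/s).

    ΔD* at the gate equals the uniform-profile flow term −ln|sinc|/b (the
    isotropic pulsatile share cancels between directions), so the bisection
    inverts the closed form directly, on the monotone branch before the first
    phase-wrap null.  ``cycle``/``flow_template`` are accepted for signature
    symmetry with the forward model; the envelope factor is 1 at the gate.
    """
    if target_delta_dstar < 0:
        raise ValueError("target_delta_dstar must be non-negative")
    if target_delta_dstar == 0:
        return 0.0
    v_null = 2.0 * np.pi / pgse.phase_per_velocity  # first |sinc| zero
    v_hi = 0.999 * v_null
    if flow_dstar(v_hi, pgse, use_nominal_b) < target_delta_dstar:
        raise ValueError("target_delta_dstar unreachable below the phase-wrap null")
    return float(brentq(
        lambda v: flow_dstar(v, pgse, use_nominal_b) - target_delta_dstar,
        0.0, v_hi, xtol=tol))


def expected_cohort_flow_dstar(v_peak: float, pgse: PGSEParams, cv: float,
                               use_nominal_b: bool = True,
                               n_nodes: int = 40) -> float:
    """Expected ΔD* at the systolic gate over a cohort whose v_peak varies
    log-normally (unit mean, coefficient of variation ``cv``) around
    ``v_peak``, by Gauss–Hermite quadrature.

    The flow term is convex in velocity, so the cohort mean exceeds the
    template animal's value (by ≈5% at cv = 0.2).
    """
    if cv == 0:
        return flow_dstar(v_peak, pgse, use_nominal_b)
    sigma = np.sqrt(np.log1p(cv * cv))
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    m = np.exp(np.sqrt(2.0) * sigma * nodes - sigma * sigma / 2.0)
    # clip extreme-tail nodes below the phase-wrap null where -ln|sinc| blows up
    v = np.minimum(v_peak * m, 0.999 * 2.0 * np.pi / pgse.phase_per_velocity)
    vals = np.array([flow_dstar(vi, pgse, use_nominal_b) for vi in v])
    return float(np.sum(weights * vals) / np.sqrt(np.pi))


def calibrate_cohort_v_peak(target_delta_dstar: float, pgse: PGSEParams,
                            cv: float, use_nominal_b: bool = True,
                            tol: float = 1e-7) -> float:
    """Template v_peak (mm/s) such that the *cohort-mean* systolic ΔD* equals
    ``target_delta_dstar`` under log-normal between-animal variability.

    The printed study values are cohort means, so preset flow amplitudes are
    calibrated at the cohort-expectation level; with ``cv = 0`` this reduces
    to :func:`calibrate_v_peak`.
    """
    if target_delta_dstar < 0:
        raise ValueError("target_delta_dstar must be non-negative")
    if target_delta_dstar == 0:
        return 0.0
    if cv == 0:
        return calibrate_v_peak(target_delta_dstar, pgse,
                                use_nominal_b=use_nominal_b, tol=tol)
    v_hi = 0.99 * 2.0 * np.pi / pgse.phase_per_velocity
    return float(brentq(
        lambda v: expected_cohort_flow_dstar(v, pgse, cv, use_nominal_b)
        - target_delta_dstar, 0.0, v_hi, xtol=tol))


# ---------------------------------------------------------------------------
# Acquisition grid and phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionParams:
    """Gated acquisition: matrix/FOV, ECG gate delay (ms), repetitions, SNR."""

    matrix: tuple[int, int, int] = (64, 64, 2)
    fov: tuple[float, float, float] = (30.0, 30.0, 2.0)
    ecg_delay: float = 25.0
    n_repetitions: int = 1
    snr: float = 40.0

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.matrix) or any(f <= 0 for f in self.fov):
            raise ValueError("matrix and fov must be positive")
        if self.ecg_delay < 0:
            raise ValueError("ecg_delay must be non-negative")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.fov[0] / self.matrix[0],
                        self.fov[1] / self.matrix[1],
                        self.fov[2] / self.matrix[2], 1.0])


@dataclass(frozen=True)
class PhantomGeometry:
    """Integer label map over the acquisition grid (voxel-index space).

    FE is the first in-plane axis, PE the second; the right perivascular
    tract extends along FE, the left tract along PE.
    """

    labels: np.ndarray
    label_names: dict = field(default_factory=lambda: dict(REGION_LABELS))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def mask(self, region: str) -> np.ndarray:
        if region not in self.label_names:
            raise KeyError(f"unknown region {region!r}")
        return self.labels == self.label_names[region]


def make_phantom(acq: AcquisitionParams) -> PhantomGeometry:
    """Deterministic ventral-brain label map on the acquisition grid.

    An elliptical "brain" of tissue holds two orthogonal perivascular tracts
    (right along FE, left along PE), a subarachnoid-space band and a small
    third-ventricle block; everything outside the ellipse is background.
    """
    nx, ny, nz = acq.matrix
    if nx < 32 or ny < 32:
        raise ValueError("matrix must be at least 32x32 in plane")
    labels2d = np.zeros((nx, ny), dtype=np.int16)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    brain = ((x - cx) / (0.45 * nx)) ** 2 + ((y - cy) / (0.45 * ny)) ** 2 <= 1.0
    labels2d[brain] = REGION_LABELS["tissue"]

    def block(x0, x1, y0, y1, name):
        labels2d[int(round(x0 * nx)):int(round(x1 * nx)),
                 int(round(y0 * ny)):int(round(y1 * ny))] = REGION_LABELS[name]

    block(0.30, 0.70, 0.78, 0.84, "SAS")
    block(0.47, 0.53, 0.47, 0.53, "third_ventricle")
    # tracts: >= 6 voxels long even at 32x32, 2 voxels wide
    block(0.16, 0.42, 0.33, 0.36, "right_PVS")   # extended along FE (axis 0)
    block(0.62, 0.65, 0.16, 0.42, "left_PVS")    # extended along PE (axis 1)

    labels = np.repeat(labels2d[:, :, None], nz, axis=2)
    return PhantomGeometry(labels=labels, affine=acq.affine)


# ---------------------------------------------------------------------------
# Compartment signal model and volume rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DWIVolume:
    """One gated image volume plus its acquisition metadata sidecar."""

    data: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        required = {"b_value_s_per_mm2", "mpg_axis", "ecg_delay_ms",
                    "repetition", "animal_id", "condition"}
        missing = required - set(self.meta)
        if missing:
            raise ValueError(f"incomplete volume meta, missing {sorted(missing)}")
        if np.any(np.asarray(self.data) < 0):
            raise ValueError("voxel values must be non-negative")


@dataclass(frozen=True)
class CompartmentSignalModel:
    """Noise-free per-region attenuation for one gated acquisition."""

    animal: AnimalParams
    pgse: PGSEParams
    ecg_delay: float
    use_nominal_b: bool = True
    n_spins: int = 20000

    def _pvs_alignment(self, region: str) -> str:
        tract_axis = "FE" if region == "right_PVS" else "PE"
        return "parallel" if self.pgse.axis == tract_axis else "perpendicular"

    def attenuation(self, region: str, seed=None) -> float:
        """Attenuation in (0, 1]; exactly 1 for the b0 acquisition."""
        if self.pgse.axis == "none":
            return 1.0
        b = effective_b(self.pgse, self.use_nominal_b)
        env = velocity_envelope(self.ecg_delay, self.animal.cycle)
        if region in ("right_PVS", "left_PVS"):
            return mc_attenuation(
                self.animal.flow, self.pgse, self.ecg_delay, self.animal.cycle,
                alignment=self._pvs_alignment(region), n_spins=self.n_spins,
                seed=seed, use_nominal_b=self.use_nominal_b)
        if region == "SAS":
            return float(np.exp(-b * (CSF_D + SAS_PULSE_AMPLITUDE * env)))
        if region == "third_ventricle":
            return float(np.exp(-b * (CSF_D + VENTRICLE_PULSE_AMPLITUDE * env)))
        if region == "tissue":
            return float(np.exp(-b * TISSUE_ADC))
        if region == "background":
            return 1.0
        raise KeyError(f"unknown region {region!r}")


def region_signals(phantom: PhantomGeometry, animal: AnimalParams,
                   pgse: PGSEParams, acq: AcquisitionParams, seed,
                   use_nominal_b: bool = True) -> dict:
    """Noise-free region signal S0 × attenuation for every phantom region.

    The Monte-Carlo attenuation seed is derived deterministically from
    ``seed``, so the noise-free model value of a rendered volume can be
    recomputed exactly.
    """
    model = CompartmentSignalModel(animal=animal, pgse=pgse,
                                   ecg_delay=acq.ecg_delay,
                                   use_nominal_b=use_nominal_b)
    mc_seed, _ = np.random.SeedSequence(seed).spawn(2)
    return {region: REGION_S0[region] * model.attenuation(region, seed=mc_seed)
            for region in phantom.label_names}


def add_rician_noise(signal: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + n1) + i·n2 with independent N(0, sigma) channels."""
    if sigma == 0:
        return np.abs(signal)
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(signal + n1, n2)


def render_volume(phantom: PhantomGeometry, animal: AnimalParams,
                  pgse: PGSEParams, acq: AcquisitionParams, seed,
                  repetition: int = 0, condition: str = "baseline",
                  use_nominal_b: bool = True) -> DWIVolume:
    """Render one gated volume: per-region noise-free signal broadcast to the
    region's voxels, then voxelwise Rician noise at ``acq.snr`` (SNR defined
    on the b0 perivascular signal)."""
    signals = region_signals(phantom, animal, pgse, acq, seed,
                             use_nominal_b=use_nominal_b)
    data = np.zeros(phantom.labels.shape, dtype=float)
    for region, value in signals.items():
        data[phantom.mask(region)] = value
    _, noise_seed = np.random.SeedSequence(seed).spawn(2)
    sigma = REGION_S0["right_PVS"] / acq.snr if np.isfinite(acq.snr) else 0.0
    data = add_rician_noise(data, sigma, np.random.default_rng(noise_seed))
    meta = {
        "b_value_s_per_mm2": effective_b(pgse, use_nominal_b),
        "mpg_axis": pgse.axis,
        "ecg_delay_ms": acq.ecg_delay,
        "repetition": repetition,
        "animal_id": animal.id,
        "condition": condition,
    }
    return DWIVolume(data=data, meta=meta)


# ---------------------------------------------------------------------------
# NIfTI + JSON sidecar I/O
# ---------------------------------------------------------------------------

def save_volume(volume: DWIVolume, path: str | Path,
                affine: np.ndarray | None = None) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz) with a JSON sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32),
                             affine if affine is not None else np.eye(4)), path)
    _sidecar_path(path).write_text(json.dumps(volume.meta, indent=1))


def load_volume(path: str | Path) -> DWIVolume:
    """Read a NIfTI volume and its JSON sidecar back into a :class:`DWIVolume`."""
    path = Path(path)
    data = np.asarray(nib.load(path).dataobj, dtype=float)
    meta = json.loads(_sidecar_path(path).read_text())
    return DWIVolume(data=data, meta=meta)


def save_phantom(phantom: PhantomGeometry, path: str | Path) -> None:
    """Write the label map as integer NIfTI-1 plus a labels.json key."""
    path = Path(path)
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), phantom.affine), path)
    (path.parent / "labels.json").write_text(json.dumps(phantom.label_names, indent=1))


def load_phantom(path: str | Path) -> PhantomGeometry:
    path = Path(path)
    img = nib.load(path)
    labels_file = path.parent / "labels.json"
    names = json.loads(labels_file.read_text()) if labels_file.exists() \
        else dict(REGION_LABELS)
    return PhantomGeometry(labels=np.asarray(img.dataobj).astype(np.int16),
                           label_names=names, affine=np.asarray(img.affine))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")
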