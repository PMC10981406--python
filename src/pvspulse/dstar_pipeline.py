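"""Pseudo-diffusion (D*) estimation from gated low b-value DWI volumes.

The estimation chain mirrors the acquisition protocol: for each gated
acquisition (one b0 volume plus one diffusion-weighted volume per in-plane
gradient axis) the mean signal over each region of interest is extracted, D*
is obtained by mono-exponential inversion of S = S0·exp(−b·D*), the left and
right perivascular tracts are combined into overall parallel and
perpendicular values (a tract is "parallel" when the gradient axis matches
its orientation), and the directionality index ΔD* = D*∥ − D*⊥ is formed.
Per-delay cohort curves and the delay of their maximum, and per-animal
repetition averages, summarise the experiments.

Negative D* values (possible when noise pushes S above S0) are retained and
flagged rather than clipped, keeping cohort means unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .dwi_forward import DWIVolume, PhantomGeometry

__all__ = [
    "RoiSignal",
    "DstarEstimate",
    "DstarRecord",
    "DelayCurve",
    "roi_mean",
    "estimate_dstar",
    "combine_bilateral",
    "records_from_volumes",
    "build_delay_curve",
    "find_peak_delay",
    "average_repetitions",
]

PVS_TRACTS = ("right_PVS", "left_PVS")
#: tract orientation: the right tract runs along FE, the left along PE
TRACT_AXIS = {"right_PVS": "FE", "left_PVS": "PE"}
CONTROL_ROIS = ("SAS", "third_ventricle")


@dataclass(frozen=True)
class RoiSignal:
    """Mean signal over one ROI of one volume, with the volume's metadata."""

    roi: str
    mean_signal: float
    n_voxels: int
    meta: dict

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.mean_signal < 0:
            raise ValueError("mean_signal must be non-negative")


class DstarEstimate(NamedTuple):
    """D* value in mm²/s plus a quality flag for noise-driven negatives."""

    value: float
    negative: bool


@dataclass(frozen=True)
class DstarRecord:
    """Combined bilateral D* for one gated acquisition.

    ``delta_dstar`` is always the exact difference D*∥ − D*⊥; control-region
    D* values (per gradient axis) ride along in ``controls``.
    """

    dstar_parallel: float
    dstar_perpendicular: float
    ecg_delay: float
    animal_id: str
    condition: str = "baseline"
    repetition: int = 0
    negative_flag: bool = False
    controls: dict = field(default_factory=dict)
    delta_dstar: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_dstar",
                           self.dstar_parallel - self.dstar_perpendicular)


@dataclass(frozen=True)
class DelayCurve:
    """Cohort statistic of a D* quantity at each ECG gate delay (sorted)."""

    delays: np.ndarray
    values: np.ndarray
    sds: np.ndarray
    direction: str

    def __post_init__(self) -> None:
        delays = np.asarray(self.delays)
        if delays.size == 0:
            raise ValueError("empty delay curve")
        if np.any(np.diff(delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if not (delays.shape == np.shape(self.values) == np.shape(self.sds)):
            raise ValueError("delays/values/sds length mismatch")


# ---------------------------------------------------------------------------
# ROI extraction and inversion
# ---------------------------------------------------------------------------

def roi_mean(volume: DWIVolume, phantom: PhantomGeometry, roi: str) -> RoiSignal:
    """Arithmetic mean voxel signal over a phantom region."""
    if volume.data.shape != phantom.labels.shape:
        raise ValueError("volume and phantom grids do not match")
    mask = phantom.mask(roi)  # KeyError for unknown labels
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"ROI {roi!r} is empty")
    return RoiSignal(roi=roi, mean_signal=float(volume.data[mask].mean()),
                     n_voxels=n, meta=dict(volume.meta))


def estimate_dstar(s0: float, s: float, b: float) -> DstarEstimate:
    """Mono-exponential inversion D* = ln(S0/S)/b of S = S0·exp(−b·D*).

    Returns the unclipped value (mm²/s) with ``negative=True`` when noise
    makes S exceed S0.
    """
    if s0 <= 0 or s <= 0:
        raise ValueError("signals must be positive")
    if b <= 0:
        raise ValueError("b must be positive")
    value = float(np.log(s0 / s) / b)
    return DstarEstimate(value=value, negative=value < 0)


def combine_bilateral(tract_dstars: Mapping) -> tuple[float, float]:
    """Average the two tracts into (parallel, perpendicular) D*.

    ``tract_dstars`` maps (tract, gradient axis) — all four of
    (right_PVS, FE), (left_PVS, PE), (right_PVS, PE), (left_PVS, FE) — to D*
    values; parallel pairs a tract with its own orientation.
    """
    def get(tract: str, axis: str) -> float:
        try:
            v = tract_dstars[(tract, axis)]
        except KeyError:
            raise ValueError(f"missing D* for tract {tract!r} at axis {axis!r}") from None
        return v.value if isinstance(v, DstarEstimate) else float(v)

    parallel = 0.5 * (get("right_PVS", "FE") + get("left_PVS", "PE"))
    perpendicular = 0.5 * (get("right_PVS", "PE") + get("left_PVS", "FE"))
    return parallel, perpendicular


def records_from_volumes(b0: DWIVolume, dw_fe: DWIVolume, dw_pe: DWIVolume,
                         phantom: PhantomGeometry) -> DstarRecord:
    """Full estimation for one gated acquisition (b0 + FE + PE volumes).

    Each repetition uses its own b0, per the protocol's per-acquisition
    b0 + two diffusion-weighted images.
    """
    if b0.meta["mpg_axis"] != "none":
        raise ValueError("first volume must be the unweighted b0 acquisition")
    tract_dstars: dict = {}
    negative = False
    controls: dict = {}
    for dw in (dw_fe, dw_pe):
        axis = dw.meta["mpg_axis"]
        if axis not in ("FE", "PE"):
            raise ValueError("diffusion-weighted volume with unknown axis")
        b = dw.meta["b_value_s_per_mm2"]
        for tract in PVS_TRACTS:
            est = estimate_dstar(roi_mean(b0, phantom, tract).mean_signal,
                                 roi_mean(dw, phantom, tract).mean_signal, b)
            tract_dstars[(tract, axis)] = est
            negative = negative or est.negative
        for roi in CONTROL_ROIS:
            controls[f"{roi}_{axis}"] = estimate_dstar(
                roi_mean(b0, phantom, roi).mean_signal,
                roi_mean(dw, phantom, roi).mean_signal, b).value
    parallel, perpendicular = combine_bilateral(tract_dstars)
    return DstarRecord(
        dstar_parallel=parallel, dstar_perpendicular=perpendicular,
        ecg_delay=float(dw_fe.meta["ecg_delay_ms"]),
        animal_id=str(b0.meta["animal_id"]),
        condition=str(b0.meta["condition"]),
        repetition=int(b0.meta["repetition"]),
        negative_flag=negative, controls=controls)


# ---------------------------------------------------------------------------
# Curves, peaks, repetition averages
# ---------------------------------------------------------------------------

def _record_value(record: DstarRecord, quantity: str) -> float:
    if quantity in ("delta_dstar", "dstar_parallel", "dstar_perpendicular"):
        return getattr(record, quantity)
    return record.controls[quantity]


def build_delay_curve(records: Iterable[DstarRecord], statistic: str = "mean",
                      quantity: str = "delta_dstar") -> DelayCurve:
    """Cohort mean (± SD) of a D* quantity at each gate delay, sorted."""
    if statistic != "mean":
        raise ValueError(f"unknown statistic {statistic!r}")
    by_delay: dict = {}
    for rec in records:
        by_delay.setdefault(rec.ecg_delay, []).append(_record_value(rec, quantity))
    if not by_delay:
        raise ValueError("no records supplied")
    delays = np.array(sorted(by_delay))
    values = np.array([np.mean(by_delay[d]) for d in delays])
    sds = np.array([np.std(by_delay[d], ddof=1) if len(by_delay[d]) > 1 else 0.0
                    for d in delays])
    return DelayCurve(delays=delays, values=values, sds=sds, direction=quantity)


def find_peak_delay(curve: DelayCurve) -> float:
    """Gate delay (ms) of the curve maximum; ties resolve to the earliest
    delay.  Uses the discrete delay grid only — no interpolation."""
    if curve.delays.size < 2:
        raise ValueError("need at least two delays to locate a peak")
    return float(curve.delays[int(np.argmax(curve.values))])


def average_repetitions(records: Sequence[DstarRecord]) -> float:
    """Per-animal summary: arithmetic mean ΔD* across repetitions."""
    records = list(records)
    if not records:
        raise ValueError("no repetitions to average")
    return float(np.mean([r.delta_dstar for r in records]))
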