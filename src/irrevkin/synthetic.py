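"""Synthetic study inputs: arterial input function, whole-blood curve,
frame schedule and a 4D digital phantom.

No measured subject curves ship with this package; the generator produces a
bolus-injection arterial plasma curve with the qualitative structure the
analysis assumes (sharp peak 1–2 min post injection, multi-exponential
tail, 60-min coverage).  All parameters are config-exposed so measured
curves can be substituted.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .curves import FrameSchedule, RateConstants, SampledCurve, TissueTAC
from .kinetics import DEFAULT_GRID_STEP, _exp_conv_uniform, _uniform_grid, simulate_tac
from .simulation import NoiseModel, frame_noise_sd

__all__ = [
    "DEFAULT_PEAK_ACTIVITY",
    "PUTAMEN",
    "InputFunctionSpec",
    "PhantomSpec",
    "make_input_function",
    "make_whole_blood",
    "default_frame_schedule",
    "make_phantom",
    "default_study_inputs",
]

#: Peak amplitude of the default input function, in the package's nominal
#: activity units.  The absolute scale is a calibration convention: it is
#: chosen once so that the nominal noise scale factors sf = 7 / 20 / 120
#: reproduce the ROI / small-ROI / HRRT-voxel variability regimes reported
#: for this tracer (CoV(Ki) of the fixed-VB basis-function fit ≈ 40% at
#: sf = 120 under the default putamen kinetics); see docs/methods.md.
DEFAULT_PEAK_ACTIVITY = 600_000.0

#: Average putamen kinetics of the tracer (healthy gray matter).
PUTAMEN = RateConstants(K1=0.31, k2=0.1, k3=0.049, VB=0.05)


@dataclass(frozen=True)
class InputFunctionSpec:
    """Tri-exponential bolus input function (Feng-type model).

    For t >= t0 (with u = t - t0, minutes):

        Ca(t) = (A1·u - A2 - A3)·e^{-lam1·u} + A2·e^{-lam2·u} + A3·e^{-lam3·u}

    and 0 before t0.  The curve is continuous at t0 and is peak-normalized
    to ``peak_activity``.
    """

    t0: float = 0.5  # min, tracer appearance time
    a1: float = 800.0
    a2: float = 4.0  # tail amplitudes small enough that the gray-matter
    a3: float = 1.0  # TAC peaks at 120-260 s and then plateaus

    lam1: float = 4.0  # min⁻¹, bolus washout
    lam2: float = 0.12  # min⁻¹, intermediate tail
    lam3: float = 0.01  # min⁻¹, slow tail
    peak_activity: float = DEFAULT_PEAK_ACTIVITY
    duration_min: float = 62.5
    grid_step: float = DEFAULT_GRID_STEP

    def __post_init__(self) -> None:
        if not (self.lam1 > self.lam2 > self.lam3 > 0):
            raise ValueError("need lam1 > lam2 > lam3 > 0")
        if self.t0 < 0 or self.peak_activity <= 0:
            raise ValueError("t0 must be >= 0 and peak_activity > 0")


def make_input_function(
    spec: InputFunctionSpec | None = None, check_peak: bool = True
) -> SampledCurve:
    """Generate the metabolite-corrected arterial plasma curve.

    Sampled at 1-s resolution out to ``duration_min``.  If ``check_peak``,
    the simulated gray-matter (putamen) TAC peak time is verified to fall in
    the physiological window; parameterizations peaking outside [60, 400] s
    trigger a warning.
    """
    spec = spec or InputFunctionSpec()
    grid = _uniform_grid(spec.duration_min, spec.grid_step)
    u = grid - spec.t0
    pos = u > 0
    values = np.zeros_like(grid)
    up = u[pos]
    values[pos] = (
        (spec.a1 * up - spec.a2 - spec.a3) * np.exp(-spec.lam1 * up)
        + spec.a2 * np.exp(-spec.lam2 * up)
        + spec.a3 * np.exp(-spec.lam3 * up)
    )
    values = np.clip(values, 0.0, None)
    peak = values.max()
    if peak <= 0:
        raise ValueError("input-function parameterization produced no peak")
    values *= spec.peak_activity / peak
    ca = SampledCurve(grid, values)
    if check_peak:
        _warn_if_tac_peak_unphysiological(ca, spec)
    return ca


def _warn_if_tac_peak_unphysiological(
    ca: SampledCurve, spec: InputFunctionSpec
) -> None:
    cb = make_whole_blood(ca)
    grid = ca.times
    rc = PUTAMEN
    theta = rc.theta
    int_ca = _exp_conv_uniform(0.0, ca.values, spec.grid_step)
    conv = _exp_conv_uniform(theta, ca.values, spec.grid_step)
    ct = (1 - rc.VB) * (
        (rc.K1 * rc.k3 / theta) * int_ca + (rc.K1 * rc.k2 / theta) * conv
    ) + rc.VB * cb.values
    peak_s = 60.0 * grid[int(np.argmax(ct))]
    if not (60.0 <= peak_s <= 400.0):
        warnings.warn(
            f"simulated gray-matter TAC peaks at {peak_s:.0f} s, outside the "
            "physiological window [60, 400] s",
            RuntimeWarning,
            stacklevel=3,
        )


def make_whole_blood(
    ca: SampledCurve,
    plasma_to_blood_ratio: float = 1.19,
    pf_fast: float = 0.8,
    pf_slow: float = 0.2,
    pf_tau: float = 10.0,
) -> SampledCurve:
    """Whole-blood radioactivity derived from the plasma parent curve.

    Cb(t) = [Ca(t)/pf(t)] / R with parent fraction
    pf(t) = pf_fast·e^{-t/pf_tau} + pf_slow (t in minutes) and
    plasma-to-whole-blood ratio R.  Since pf <= 1, Cb >= Ca/R everywhere.
    """
    pf = pf_fast * np.exp(-ca.times / pf_tau) + pf_slow
    return SampledCurve(ca.times, (ca.values / pf) / plasma_to_blood_ratio)


# Printed acquisition sequence after the initial pre-arrival frame (seconds).
_FRAME_DURATIONS_S = [30] + [30] * 5 + [45] + [60] * 2 + [90, 120, 210] + [300] * 10


def default_frame_schedule(end_min: float = 60.0) -> FrameSchedule:
    """The 22-frame dynamic acquisition schedule.

    First frame fixed at 30 s (standing in for the scanner's variable-length
    pre-arrival frame), then 5x30 s, 1x45 s, 2x60 s, 1x90 s, 1x120 s,
    1x210 s and 10x300 s.  Frames are truncated so the last ends at
    ``end_min`` (the printed sequence sums to 62.75 min).
    """
    edges_s = np.concatenate([[0.0], np.cumsum(_FRAME_DURATIONS_S)])
    end_s = end_min * 60.0
    frames = []
    for s, e in zip(edges_s[:-1], edges_s[1:]):
        if s >= end_s:
            break
        frames.append((s / 60.0, min(e, end_s) / 60.0))
    return FrameSchedule(np.array(frames))


def _default_regions() -> dict[str, RateConstants]:
    return {
        "gm_baseline": PUTAMEN,
        "gm_blocked": PUTAMEN.replace(k3=PUTAMEN.k3 * 0.1),
        "wm": RateConstants(K1=0.16, k2=0.06, k3=0.06, VB=0.05),
        "vessel": RateConstants(K1=0.0, k2=0.0, k3=0.0, VB=1.0),
        "background": RateConstants(K1=0.0, k2=0.0, k3=0.0, VB=0.0),
    }


@dataclass
class PhantomSpec:
    """Digital 4D phantom layout: labeled slabs of homogeneous kinetics."""

    shape: tuple[int, int, int] = (32, 32, 8)
    regions: dict[str, RateConstants] = field(default_factory=_default_regions)
    sf: float = 0.0
    seed: int = 0
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        required = {"gm_baseline", "gm_blocked", "wm", "vessel", "background"}
        unknown = set(self.regions) - required
        if unknown:
            raise ValueError(f"unknown region label(s): {sorted(unknown)}")
        missing = required - set(self.regions)
        if missing:
            raise ValueError(f"missing region label(s): {sorted(missing)}")


#: Stable integer codes for the phantom label map.
REGION_CODES = {
    "background": 0,
    "gm_baseline": 1,
    "gm_blocked": 2,
    "wm": 3,
    "vessel": 4,
}


def _build_label_map(shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int16)

    def margin(n: int) -> int:
        return min(max(1, n // 8), max(0, (n - 2) // 2))

    y0, y1 = margin(ny), ny - margin(ny)
    z0, z1 = margin(nz), nz - margin(nz)

    def sl(f0, f1):
        return slice(int(round(f0 * nx)), int(round(f1 * nx)))

    inner = (slice(y0, y1), slice(z0, z1))
    labels[(sl(0.05, 0.35), *inner)] = REGION_CODES["gm_baseline"]
    labels[(sl(0.35, 0.60), *inner)] = REGION_CODES["gm_blocked"]
    labels[(sl(0.60, 0.82), *inner)] = REGION_CODES["wm"]
    labels[(sl(0.82, 0.92), *inner)] = REGION_CODES["vessel"]
    return labels


def make_phantom(
    spec: PhantomSpec,
    ca: SampledCurve,
    cb: SampledCurve,
    schedule: FrameSchedule,
):
    """Generate a 4D dynamic phantom plus ground-truth parameter maps.

    Every voxel of a region shares the region's noise-free TAC; frame noise
    is drawn independently per voxel.  Returns
    ``(image4d, truth_maps, label_map, sidecar)`` where ``image4d`` is a
    ``nibabel.Nifti1Image``, ``truth_maps`` maps parameter names to 3D
    arrays, and ``sidecar`` holds BIDS-style frame timing in seconds.
    """
    import nibabel as nib

    labels = _build_label_map(spec.shape)
    F = schedule.n_frames
    data = np.zeros(spec.shape + (F,), dtype=np.float64)
    truth = {
        p: np.zeros(spec.shape) for p in ("Ki", "lambda_k3", "K1", "k2", "k3", "VB")
    }
    rng = np.random.default_rng(spec.seed)
    noise = NoiseModel(sf=spec.sf) if spec.sf > 0 else None

    for name, code in REGION_CODES.items():
        mask = labels == code
        nvox = int(mask.sum())
        if nvox == 0:
            continue
        rc = spec.regions[name]
        clean = simulate_tac(rc, ca, cb, schedule)
        if noise is not None and name != "background":
            sd = frame_noise_sd(noise, clean)
            vox = clean.values[None, :] + sd[None, :] * rng.standard_normal(
                (nvox, F)
            )
        else:
            vox = np.broadcast_to(clean.values, (nvox, F)).copy()
        data[mask] = vox
        theta = rc.theta
        truth["Ki"][mask] = rc.K1 * rc.k3 / theta if theta > 0 else 0.0
        truth["lambda_k3"][mask] = (rc.K1 / rc.k2) * rc.k3 if rc.k2 > 0 else 0.0
        truth["K1"][mask] = rc.K1
        truth["k2"][mask] = rc.k2
        truth["k3"][mask] = rc.k3
        truth["VB"][mask] = rc.VB

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(data, affine)
    sidecar = {
        "FrameTimesStart": (schedule.starts * 60.0).tolist(),
        "FrameDuration": (schedule.durations * 60.0).tolist(),
    }
    return img, truth, labels, sidecar


def default_study_inputs(
    end_min: float = 60.0,
) -> tuple[SampledCurve, SampledCurve, FrameSchedule]:
    """Convenience triple (Ca, Cb, schedule) with all defaults."""
    ca = make_input_function()
    cb = make_whole_blood(ca)
    return ca, cb, default_frame_schedule(end_min)
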