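"""Forward model of the irreversible 2TCM and exponential-convolution primitives.

The tissue curve of an irreversible two-tissue compartment model with
arterial plasma input Ca(t) and whole-blood activity Cb(t) is

    CT(t) = (1-VB)·(K1·k3/θ)·∫₀ᵗ Ca dτ + (1-VB)·(K1·k2/θ)·e^{-θt}⊗Ca(t) + VB·Cb(t)

with θ = k2 + k3.  For θ → 0 the model degenerates continuously to pure
integration, CT = (1-VB)·K1·∫Ca + VB·Cb.

All continuous-time work happens on a uniform fine grid (default step 1 s).
The exponential convolution uses the exact recursive update for a
piecewise-linear input, which stays accurate for large θ where naive
quadrature loses the fast transient.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import lfilter

from .curves import (
    FrameSchedule,
    Macroparameters,
    RateConstants,
    SampledCurve,
    TissueTAC,
)

__all__ = [
    "DEFAULT_GRID_STEP",
    "convolve_exp",
    "simulate_tac",
    "macroparameters",
    "frame_average",
    "TacModel",
]

#: Fine-grid step in minutes (1 second).
DEFAULT_GRID_STEP = 1.0 / 60.0


def _uniform_grid(t_end: float, step: float) -> np.ndarray:
    n = int(round(t_end / step))
    if abs(n * step - t_end) > 1e-9:
        n = int(np.ceil(t_end / step - 1e-12))
    return np.arange(n + 1) * step


def _exp_conv_uniform(theta: float, f: np.ndarray, h: float) -> np.ndarray:
    """e^{-θt} ⊗ f on a uniform grid of step h, f piecewise linear.

    Over one step the update is exact:
        y[k] = E·y[k-1] + c0·f[k-1] + c1·f[k]
    with E = e^{-θh}, c1 = (h - α)/(θh), c0 = α - c1, α = (1 - E)/θ.
    θ = 0 reduces to the running trapezoidal integral.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if theta == 0.0:
        out = np.empty_like(f)
        out[0] = 0.0
        np.cumsum(0.5 * h * (f[1:] + f[:-1]), out=out[1:])
        return out
    E = float(np.exp(-theta * h))
    alpha = -np.expm1(-theta * h) / theta
    c1 = (h - alpha) / (theta * h)
    c0 = alpha - c1
    drive = np.empty_like(f)
    drive[0] = 0.0
    drive[1:] = c0 * f[:-1] + c1 * f[1:]
    return lfilter([1.0], [1.0, -E], drive)


def convolve_exp(
    theta: float, curve: SampledCurve, grid_step: float = DEFAULT_GRID_STEP
) -> SampledCurve:
    """Convolution e^{-θt} ⊗ curve evaluated on a uniform grid.

    The result spans [0, curve.last_time]; the value at t = 0 is 0
    (causality).  The curve is interpolated linearly onto the grid and taken
    as 0 before its first sample.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    grid = _uniform_grid(curve.last_time, grid_step)
    f = curve.interp(grid)
    return SampledCurve(grid, _exp_conv_uniform(theta, f, grid_step))


def frame_average(
    grid: np.ndarray, values: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Time-average of a fine-grid curve over each frame interval."""
    h = grid[1] - grid[0]
    cum = np.empty_like(values)
    cum[0] = 0.0
    np.cumsum(0.5 * h * (values[1:] + values[:-1]), out=cum[1:])
    i_start = np.interp(schedule.starts, grid, cum)
    i_end = np.interp(schedule.ends, grid, cum)
    return (i_end - i_start) / schedule.durations


def _frame_midpoint(
    grid: np.ndarray, values: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    return np.interp(schedule.midpoints, grid, values)


def _sample_frames(grid, values, schedule, sampling: str) -> np.ndarray:
    if sampling == "average":
        return frame_average(grid, values, schedule)
    if sampling == "midpoint":
        return _frame_midpoint(grid, values, schedule)
    raise ValueError(f"unknown frame sampling mode: {sampling!r}")


def _check_coverage(curve: SampledCurve, t_end: float, name: str) -> None:
    if curve.last_time < t_end - 1e-9:
        raise ValueError(
            f"{name} covers only [0, {curve.last_time:.3f}] min but the frame "
            f"schedule extends to {t_end:.3f} min"
        )


def simulate_tac(
    rc: RateConstants,
    ca: SampledCurve,
    cb: SampledCurve,
    schedule: FrameSchedule,
    grid_step: float = DEFAULT_GRID_STEP,
    sampling: str = "average",
) -> TissueTAC:
    """Noise-free frame-sampled tissue TAC of the irreversible 2TCM.

    Frame values are time-averages of the continuous model over each frame
    (PET frames report mean activity); ``sampling='midpoint'`` selects
    instantaneous midpoint evaluation instead.
    """
    t_end = schedule.end_time
    _check_coverage(ca, t_end, "input function")
    _check_coverage(cb, t_end, "whole-blood curve")
    grid = _uniform_grid(t_end, grid_step)
    caf = ca.interp(grid)
    cbf = cb.interp(grid)
    theta = rc.theta
    int_ca = _exp_conv_uniform(0.0, caf, grid_step)
    if theta <= 0.0:
        tissue = rc.K1 * int_ca
    else:
        conv = _exp_conv_uniform(theta, caf, grid_step)
        tissue = (rc.K1 * rc.k3 / theta) * int_ca + (rc.K1 * rc.k2 / theta) * conv
    ct = (1.0 - rc.VB) * tissue + rc.VB * cbf
    return TissueTAC(schedule, _sample_frames(grid, ct, schedule, sampling))


def macroparameters(rc: RateConstants) -> Macroparameters:
    """Macroparameters Ki, λk3, VND and θ from the microparameters.

    k2 = 0 leaves VND and λk3 undefined (returned as inf with a warning);
    Ki is still defined as long as k2 + k3 > 0.
    """
    theta = rc.theta
    ki = rc.K1 * rc.k3 / theta if theta > 0 else 0.0
    if rc.k2 > 0:
        vnd = rc.K1 / rc.k2
        lam_k3 = vnd * rc.k3
    else:
        warnings.warn(
            "k2 = 0: VND and lambda_k3 are undefined", RuntimeWarning, stacklevel=2
        )
        vnd = np.inf if rc.K1 > 0 else np.nan
        lam_k3 = np.inf if (rc.K1 > 0 and rc.k3 > 0) else np.nan
    return Macroparameters(Ki=ki, lambda_k3=lam_k3, VND=vnd, theta=theta)


class TacModel:
    """Cached forward model on a fixed (Ca, Cb, schedule) triple.

    Pre-interpolates the blood curves onto the fine grid so that repeated
    evaluations (nonlinear fitting, Monte Carlo) cost one exponential
    convolution each.
    """

    def __init__(
        self,
        ca: SampledCurve,
        cb: SampledCurve,
        schedule: FrameSchedule,
        grid_step: float = DEFAULT_GRID_STEP,
        sampling: str = "average",
    ) -> None:
        t_end = schedule.end_time
        _check_coverage(ca, t_end, "input function")
        _check_coverage(cb, t_end, "whole-blood curve")
        self.schedule = schedule
        self.grid_step = float(grid_step)
        self.sampling = sampling
        self.grid = _uniform_grid(t_end, grid_step)
        self.ca_fine = ca.interp(self.grid)
        self.cb_fine = cb.interp(self.grid)
        self.int_ca_fine = _exp_conv_uniform(0.0, self.ca_fine, self.grid_step)
        self.int_ca_frames = self._frames(self.int_ca_fine)
        self.ca_frames = self._frames(self.ca_fine)
        self.cb_frames = self._frames(self.cb_fine)

    def _frames(self, values: np.ndarray) -> np.ndarray:
        return _sample_frames(self.grid, values, self.schedule, self.sampling)

    def basis_frames(self, theta: float) -> np.ndarray:
        """Frame-sampled e^{-θt} ⊗ Ca."""
        return self._frames(_exp_conv_uniform(theta, self.ca_fine, self.grid_step))

    def tissue_frames(self, K1: float, k2: float, k3: float) -> np.ndarray:
        """Frame-sampled tissue signal (VB = 0 part of the model)."""
        theta = k2 + k3
        if theta <= 0.0:
            fine = K1 * self.int_ca_fine
        else:
            conv = _exp_conv_uniform(theta, self.ca_fine, self.grid_step)
            fine = (K1 * k3 / theta) * self.int_ca_fine + (K1 * k2 / theta) * conv
        return self._frames(fine)

    def frames(self, rc: RateConstants) -> np.ndarray:
        return (1.0 - rc.VB) * self.tissue_frames(rc.K1, rc.k2, rc.k3) + (
            rc.VB * self.cb_frames
        )
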