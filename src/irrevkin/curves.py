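"""Containers for sampled blood curves, frame schedules and tissue TACs.

All times are minutes post injection; all activities are decay-corrected
activity concentrations (nominally kBq·mL⁻¹; the absolute scale of the
synthetic curves is a calibration convention, see :mod:`irrevkin.synthetic`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampledCurve",
    "FrameSchedule",
    "TissueTAC",
    "RateConstants",
    "Macroparameters",
]


@dataclass
class SampledCurve:
    """A time-ordered activity curve (plasma input, whole blood, model output).

    Parameters
    ----------
    times :
        Sample times in minutes, strictly increasing, first sample at t >= 0.
    values :
        Activity concentration at each sample time.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size < 2:
            raise ValueError("curve needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("curve times must be strictly increasing")
        if self.times[0] < 0:
            raise ValueError("first sample time must be >= 0")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError("curve contains non-finite entries")

    @property
    def last_time(self) -> float:
        return float(self.times[-1])

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``t``.

        The curve is taken to be 0 before its first sample (tracer not yet
        arrived).  Requests beyond the last sample raise: silent extrapolation
        would corrupt the running integral of the input function.
        """
        t = np.asarray(t, dtype=float)
        if t.size and float(np.max(t)) > self.last_time + 1e-9:
            raise ValueError(
                f"requested time {np.max(t):.4f} min exceeds curve support "
                f"({self.last_time:.4f} min)"
            )
        return np.interp(t, self.times, self.values, left=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "activity_kBq_per_mL": self.values}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampledCurve":
        return cls(
            np.asarray(df["time_min"], dtype=float),
            np.asarray(df["activity_kBq_per_mL"], dtype=float),
        )


@dataclass
class FrameSchedule:
    """Ordered, non-overlapping PET frame intervals in minutes."""

    frames: np.ndarray  # shape (n_frames, 2): [t_start, t_end]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != 2:
            raise ValueError("frames must have shape (n, 2)")
        if self.frames.shape[0] < 1:
            raise ValueError("schedule needs at least one frame")
        if not np.all(self.frames[:, 1] > self.frames[:, 0]):
            raise ValueError("every frame must satisfy t_end > t_start")
        if not np.all(self.frames[1:, 0] >= self.frames[:-1, 1] - 1e-12):
            raise ValueError("frames must be ascending and non-overlapping")
        if self.frames[0, 0] < 0:
            raise ValueError("first frame must start at t >= 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def starts(self) -> np.ndarray:
        return self.frames[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.frames[:, 1]

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.frames[:, 0] + self.frames[:, 1])

    @property
    def durations(self) -> np.ndarray:
        return self.frames[:, 1] - self.frames[:, 0]

    @property
    def end_time(self) -> float:
        return float(self.frames[-1, 1])

    def to_frame(self) -> pd.DataFrame:
        # On-disk representation is in seconds.
        return pd.DataFrame(
            {
                "start_s": np.round(self.frames[:, 0] * 60.0, 6),
                "end_s": np.round(self.frames[:, 1] * 60.0, 6),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrameSchedule":
        frames = np.column_stack(
            [np.asarray(df["start_s"], float), np.asarray(df["end_s"], float)]
        ) / 60.0
        return cls(frames)


@dataclass
class TissueTAC:
    """Frame-averaged, decay-corrected tissue time-activity curve."""

    schedule: FrameSchedule
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.values.size != self.schedule.n_frames:
            raise ValueError("one value per frame required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC contains non-finite entries")

    def with_values(self, values: np.ndarray) -> "TissueTAC":
        return TissueTAC(self.schedule, values)


@dataclass(frozen=True)
class RateConstants:
    """Microparameters of the irreversible two-tissue compartment model.

    The trapping compartment is irreversible: k4 is identically zero.
    """

    K1: float  # mL·cm⁻³·min⁻¹, plasma-to-tissue delivery
    k2: float  # min⁻¹, efflux from the free/non-specific compartment
    k3: float  # min⁻¹, irreversible trapping rate
    VB: float = 0.0  # fractional blood volume
    k4: float = 0.0  # fixed at 0 (irreversibility)

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise ValueError("rate constants must be non-negative")
        # VB = 1 is a pure-blood voxel (phantom vessel); fits require VB < 1.
        if not (0 <= self.VB <= 1):
            raise ValueError("VB must lie in [0, 1]")
        if self.k4 != 0:
            raise ValueError("the model is irreversible: k4 must be 0")

    @property
    def theta(self) -> float:
        return self.k2 + self.k3

    def replace(self, **kwargs) -> "RateConstants":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class Macroparameters:
    """Composite parameters derived from the microparameters."""

    Ki: float  # net influx rate K1·k3/(k2+k3), mL·cm⁻³·min⁻¹
    lambda_k3: float  # (K1/k2)·k3, flow-insensitive binding index
    VND: float  # non-displaceable distribution volume K1/k2, mL·cm⁻³
    theta: float  # k2+k3, min⁻¹
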