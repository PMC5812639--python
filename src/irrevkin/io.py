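"""Readers and writers for the on-disk formats.

Curves and schedules travel as TSV; dynamic images and parametric maps as
NIfTI-1 with a BIDS-PET style JSON frame-timing sidecar; fit configuration
as YAML or JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .curves import FrameSchedule, SampledCurve
from .estimators import FitConfig

__all__ = [
    "read_curve_tsv",
    "write_curve_tsv",
    "read_schedule_tsv",
    "write_schedule_tsv",
    "read_frame_sidecar",
    "write_frame_sidecar",
    "load_fit_config",
    "load_image4d",
    "save_map",
]


def read_curve_tsv(path: str | Path) -> SampledCurve:
    df = pd.read_csv(path, sep="\t")
    for col in ("time_min", "activity_kBq_per_mL"):
        if col not in df.columns:
            raise ValueError(f"curve TSV {path} is missing column {col!r}")
    return SampledCurve.from_frame(df)


def write_curve_tsv(curve: SampledCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)


def read_schedule_tsv(path: str | Path) -> FrameSchedule:
    df = pd.read_csv(path, sep="\t")
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise ValueError(f"schedule TSV {path} is missing column {col!r}")
    return FrameSchedule.from_frame(df)


def write_schedule_tsv(schedule: FrameSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, sep="\t", index=False)


def read_frame_sidecar(path: str | Path) -> FrameSchedule:
    """Frame schedule from a BIDS-PET style JSON sidecar (times in seconds)."""
    with open(path) as fh:
        meta = json.load(fh)
    starts = np.asarray(meta["FrameTimesStart"], dtype=float)
    durations = np.asarray(meta["FrameDuration"], dtype=float)
    frames = np.column_stack([starts, starts + durations]) / 60.0
    return FrameSchedule(frames)


def write_frame_sidecar(schedule: FrameSchedule, path: str | Path) -> None:
    meta = {
        "FrameTimesStart": (schedule.starts * 60.0).tolist(),
        "FrameDuration": (schedule.durations * 60.0).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1)


def load_fit_config(path: str | Path) -> FitConfig:
    """Fit configuration from YAML or JSON.

    Recognized keys: ``theta_min``, ``theta_max``, ``n_basis``,
    ``vb_mode`` (fixed|variable), ``vb_value``, ``tstar_min``, ``weights``
    (model|uniform), ``method``.
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    kwargs = {}
    if "vb_mode" in cfg:
        mode = cfg.pop("vb_mode")
        if mode not in ("fixed", "variable"):
            raise ValueError("vb_mode must be 'fixed' or 'variable'")
        kwargs["method"] = "bafpic_fixed" if mode == "fixed" else "bafpic_variable"
    if "method" in cfg:
        kwargs["method"] = cfg.pop("method")
    if "tstar_min" in cfg:
        kwargs["tstar"] = float(cfg.pop("tstar_min"))
    for key in ("theta_min", "theta_max", "vb_value", "tstar"):
        if key in cfg:
            kwargs[key] = float(cfg.pop(key))
    if "n_basis" in cfg:
        kwargs["n_basis"] = int(cfg.pop("n_basis"))
    if "weights" in cfg:
        kwargs["weights"] = str(cfg.pop("weights"))
    if cfg:
        raise ValueError(f"unknown fit-config keys: {sorted(cfg)}")
    return FitConfig(**kwargs)


def load_image4d(path: str | Path) -> nib.Nifti1Image:
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path} is not a 4D image")
    return img


def save_map(
    data: np.ndarray, affine: np.ndarray, path: str | Path,
    header: nib.Nifti1Header | None = None,
) -> None:
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine, header), str(path))
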