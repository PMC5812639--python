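"""Voxelwise parametric-map generation.

The basis set (and its per-θ QR factorizations) is built once and reused
for every voxel, so the per-voxel cost is a handful of small
back-substitutions.  Map values are, by construction, identical to calling
the estimator directly on the voxel's TAC.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .curves import FrameSchedule, SampledCurve, TissueTAC
from .estimators import (
    BasisSet,
    FitConfig,
    build_basis,
    fit_bafpic_fixed_vb,
    fit_bafpic_variable_vb,
    fit_patlak,
)

__all__ = ["ParametricMaps", "voxelwise_map", "region_summary", "mask_from_activity"]

MAP_NAMES = ("Ki", "lambda_k3", "K1", "k2", "k3", "theta_hat", "wrss", "vb", "fit_flag")

_FLAG_CODES = {
    None: 0,
    "negative_params": 1,
    "degenerate": 2,
    "rank_deficient": 3,
    "some_thetas_skipped": 4,
}


@dataclass
class ParametricMaps:
    """3D parameter maps sharing geometry with the source 4D image.

    Out-of-mask voxels carry NaN (the fit-flag map uses -1).
    """

    maps: dict[str, np.ndarray]
    affine: np.ndarray
    mask: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def save(self, out_dir: str | Path, prefix: str = "map") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, data in self.maps.items():
            path = out_dir / f"{prefix}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(data.astype(np.float32), self.affine), path)
            written.append(path)
        return written


def mask_from_activity(
    image4d: np.ndarray | nib.Nifti1Image, threshold_fraction: float = 0.05
) -> np.ndarray:
    """Voxels whose time-summed activity exceeds a fraction of the robust
    (99.9th percentile) image maximum."""
    data = image4d.get_fdata() if hasattr(image4d, "get_fdata") else image4d
    total = data.sum(axis=-1)
    robust_max = float(np.percentile(total, 99.9))
    if robust_max <= 0:
        return np.zeros(total.shape, dtype=bool)
    return total >= threshold_fraction * robust_max


def voxelwise_map(
    image4d: nib.Nifti1Image | np.ndarray,
    schedule: FrameSchedule,
    ca: SampledCurve,
    cb: SampledCurve,
    config: FitConfig | None = None,
    mask: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    clamp_negative: bool = False,
    also_patlak: bool = False,
    affine: np.ndarray | None = None,
) -> ParametricMaps:
    """Fit every in-mask voxel of a dynamic image.

    Defaults to the basis-function estimator with fixed VB = 5%,
    θ ∈ [0.06, 3] min⁻¹ and 50 basis members.  ``also_patlak`` adds a
    ``Ki_patlak`` map computed in the same pass.  ``clamp_negative``
    clamps negative rate constants and macroparameters to 0 in the output
    maps (flagged voxels keep their flag either way).
    """
    config = config or FitConfig()
    if hasattr(image4d, "get_fdata"):
        data = image4d.get_fdata()
        affine = image4d.affine if affine is None else affine
    else:
        data = np.asarray(image4d, dtype=float)
        affine = np.eye(4) if affine is None else affine
    if data.ndim != 4:
        raise ValueError("dynamic image must be 4D")
    if data.shape[3] != schedule.n_frames:
        raise ValueError(
            f"image has {data.shape[3]} frames but the schedule defines "
            f"{schedule.n_frames}"
        )
    shape = data.shape[:3]
    if mask is None:
        mask = mask_from_activity(data)
    if mask.shape != shape:
        raise ValueError("mask geometry does not match the image")

    use_patlak = config.method == "patlak"
    basis: BasisSet | None = None
    if not use_patlak:
        basis = build_basis(
            ca, cb, schedule,
            theta_min=config.theta_min, theta_max=config.theta_max,
            n=config.n_basis, weights=weights,
        )

    maps = {name: np.full(shape, np.nan) for name in MAP_NAMES}
    maps["fit_flag"] = np.full(shape, -1.0)
    if also_patlak or use_patlak:
        maps["Ki_patlak"] = np.full(shape, np.nan)

    clampable = ("Ki", "lambda_k3", "K1", "k2", "k3")
    template = TissueTAC(schedule, np.zeros(schedule.n_frames))
    for idx in np.argwhere(mask):
        i, j, k = idx
        tac = template.with_values(data[i, j, k])
        if use_patlak:
            res = fit_patlak(tac, ca, cb, tstar=config.tstar, vb=config.vb_value)
            maps["Ki_patlak"][i, j, k] = res.Ki
            maps["fit_flag"][i, j, k] = 0.0
            continue
        if config.method == "bafpic_fixed":
            res = fit_bafpic_fixed_vb(tac, basis, config.vb_value)
        else:
            res = fit_bafpic_variable_vb(tac, basis)
        values = {
            "Ki": res.Ki, "lambda_k3": res.lambda_k3, "K1": res.K1,
            "k2": res.k2, "k3": res.k3, "theta_hat": res.theta_hat,
            "wrss": res.wrss, "vb": res.vb_hat,
        }
        flag = res.flag
        if flag is None and any(
            np.isfinite(values[p]) and values[p] < 0 for p in clampable
        ):
            flag = "negative_params"
        if clamp_negative:
            for p in clampable:
                if np.isfinite(values[p]):
                    values[p] = max(values[p], 0.0)
        for name, v in values.items():
            maps[name][i, j, k] = v
        maps["fit_flag"][i, j, k] = float(_FLAG_CODES.get(flag, 5))
        if also_patlak:
            pres = fit_patlak(tac, ca, cb, tstar=config.tstar, vb=config.vb_value)
            maps["Ki_patlak"][i, j, k] = pres.Ki

    return ParametricMaps(maps=maps, affine=np.asarray(affine), mask=mask)


def region_summary(
    maps: ParametricMaps,
    labels: np.ndarray,
    label_names: dict[str, int] | None = None,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-label mean/SD/voxel-count of every map.

    ``reference`` may hold a per-label table of ROI-level fits (columns =
    parameter names, index = label names); matching columns get
    Bland-Altman-style ``diff_<param>`` columns (map mean − reference).
    """
    if labels.shape != maps.mask.shape:
        raise ValueError("label geometry does not match the maps")
    if label_names is None:
        label_names = {str(code): int(code) for code in np.unique(labels)}
    rows = []
    for name, code in label_names.items():
        region = labels == code
        row: dict[str, float | str] = {"label": name, "code": code}
        for map_name, data in maps.maps.items():
            vals = data[region]
            vals = vals[np.isfinite(vals)]
            row[f"n_{map_name}"] = int(vals.size)
            row[f"mean_{map_name}"] = float(np.mean(vals)) if vals.size else np.nan
            row[f"sd_{map_name}"] = (
                float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
            )
        value_maps = [m for m in maps.maps if m != "fit_flag"]
        row["flag"] = (
            "empty" if all(row.get(f"n_{m}", 0) == 0 for m in value_maps) else ""
        )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("label")
    if reference is not None:
        for col in reference.columns:
            mean_col = f"mean_{col}"
            if mean_col in df.columns:
                df[f"diff_{col}"] = df[mean_col] - reference[col]
    return df
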