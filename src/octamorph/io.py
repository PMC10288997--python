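"""Readers and writers: images, masks, metric tables, configuration.

Images are 8/16-bit grayscale PNG or TIFF; masks are 0/255 PNG; metric
tables are tidy UTF-8 CSV with one row per (eye, plexus, region); the
configuration is a single JSON document of named parameter blocks.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .core import (
    DEFAULT_FOV_MM,
    METRIC_NAMES,
    EnFaceImage,
    EyeRecord,
    Group,
    Laterality,
    Plexus,
    VesselMask,
)

_TABLE_ID_COLUMNS = ["subject", "eye", "group", "age", "bmi", "bcva", "plexus", "region"]


def _load_gray(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        raise ValueError(f"{path}: color image with shape {arr.shape}; expected grayscale")
    if arr.ndim != 2:
        raise ValueError(f"{path}: unsupported array of ndim {arr.ndim}")
    return arr


def read_enface(
    path: str | Path,
    plexus: Plexus | str,
    laterality: Laterality | str,
    fov_mm: float = DEFAULT_FOV_MM,
) -> EnFaceImage:
    """Read a grayscale angiogram and min-max normalize it to [0, 1].

    Non-square or color inputs are rejected.  Sizes other than 304 are
    accepted; the physical pixel size is always ``fov_mm / width``.
    A constant-valued image normalizes to all zeros.
    """
    arr = _load_gray(path).astype(float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(
            f"{path}: en-face image must be square, got {arr.shape[0]}x{arr.shape[1]}"
        )
    lo, hi = arr.min(), arr.max()
    arr = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    return EnFaceImage(pixels=arr, plexus=Plexus(plexus), laterality=Laterality(laterality), fov_mm=fov_mm)


def read_mask(path: str | Path, fov_mm: float = DEFAULT_FOV_MM) -> VesselMask:
    """Read a 0/255 PNG (or TIFF) binary mask; any nonzero pixel is foreground."""
    arr = _load_gray(path)
    return VesselMask(pixels=arr > 0, pixel_size_mm=fov_mm / arr.shape[1])


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean array as an 8-bit 0/255 PNG/TIFF."""
    arr = (np.asarray(mask).astype(bool) * np.uint8(255))
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def records_to_table(records: Sequence[EyeRecord]) -> pd.DataFrame:
    """Flatten eye records into a tidy frame, one row per (eye, plexus, region)."""
    reference: list[str] | None = None
    rows = []
    for rec in records:
        for plexus, regions in rec.metrics.items():
            for region, metrics in regions.items():
                names = sorted(metrics)
                if reference is None:
                    reference = names
                elif names != reference:
                    raise ValueError(
                        f"record {rec.subject_id}/{rec.eye.value} {plexus}/{region} has "
                        f"metric set {names}, expected {reference}"
                    )
                row = {
                    "subject": rec.subject_id,
                    "eye": rec.eye.value,
                    "group": rec.group.value,
                    "age": rec.age,
                    "bmi": rec.bmi,
                    "bcva": rec.bcva,
                    "plexus": str(getattr(plexus, "value", plexus)),
                    "region": region,
                }
                row.update(metrics)
                rows.append(row)
    metric_cols = reference if reference is not None else list(METRIC_NAMES)
    ordered = [m for m in METRIC_NAMES if m in metric_cols]
    ordered += [m for m in metric_cols if m not in ordered]
    return pd.DataFrame(rows, columns=_TABLE_ID_COLUMNS + ordered)


def write_metrics_table(records: Sequence[EyeRecord], path: str | Path) -> pd.DataFrame:
    """Write eye records to CSV; round-trip preserves values to 1e-9."""
    table = records_to_table(records)
    table.to_csv(path, index=False, float_format="%.12g")
    return table


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def table_to_records(table: pd.DataFrame) -> list[EyeRecord]:
    """Inverse of :func:`records_to_table`."""
    metric_cols = [c for c in table.columns if c not in _TABLE_ID_COLUMNS]
    records: dict[tuple[str, str], EyeRecord] = {}
    for _, row in table.iterrows():
        key = (str(row["subject"]), str(row["eye"]))
        rec = records.get(key)
        if rec is None:
            rec = EyeRecord(
                subject_id=str(row["subject"]),
                eye=Laterality(row["eye"]),
                group=Group(row["group"]),
                age=float(row["age"]),
                bmi=float(row["bmi"]),
                bcva=float(row["bcva"]),
            )
            records[key] = rec
        rec.metrics.setdefault(str(row["plexus"]), {})[str(row["region"])] = {
            m: float(row[m]) for m in metric_cols
        }
    return list(records.values())


# ---------------------------------------------------------------------------
# Configuration

DEFAULT_CONFIG: dict = {
    "segmentation": {
        "scales_px": [2, 3, 4, 6],
        "n_orientations": 6,
        "sigma_on_f": 0.55,
        "lambda_intensity": 1.0,
        "lambda_phase": 1.0,
        "mu_regularizer": 0.1,
        "n_iterations": 300,
        "convergence_tol": 1e-4,
        "faz_close_radius_px": 6,
        "faz_center_search_px": 15,
    },
    "metrics": {
        # smoothed subpixel contour keeps circle circularity in [0.98, 1.0]
        # without biasing straight edges; crofton and chain_code available
        "perimeter_method": "contour",
        "fa_unit": "percent",  # px | mm2 | percent
        "orientation_sigma_px": 2.0,
        "direction_bins": 36,
        "box_sizes": [2, 4, 8, 16, 32, 64, 128],
        "fd_target": "mask",  # mask | skeleton
        "fd_offset_average": False,
        "tortuosity_weighting": "length",  # length | unweighted
        "min_branch_px": 5,
        "merge_radius_px": 2,
    },
    "etdrs": {
        "base_diameter_mm": 0.75,
        "center": "faz",  # faz | image
    },
    "stats": {
        "t_variant": "welch",  # welch | pooled
        "standardize_predictors": True,
        "covariates": ["age"],
        "bh_correction": False,
        "p_thresholds": [0.001, 0.05],
    },
    "simulate": {
        "n_roots": 22,
        "branch_prob": 0.05,
        "step_px": 3.0,
        "angle_sigma_deg": 8.0,
        "bifurcation_angle_deg": 35.0,
        "vessel_width_px": 2,
        "speckle_sigma": 0.15,
        "background_ramp": 0.1,
        "faz_area_mm2": 0.3,
        "faz_axial_ratio": 1.0,
        "faz_boundary_noise": 0.05,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | Path | None) -> dict:
    """Load a JSON config; missing blocks/keys fall back to defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path, "r", encoding="utf-8") as fh:
        user = json.load(fh)
    for block, values in user.items():
        if block in cfg and isinstance(values, dict):
            cfg[block].update(values)
        else:
            cfg[block] = values
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config document, for run logs."""
    payload = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
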