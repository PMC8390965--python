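"""File I/O for Mueller images, parameter maps and ROI reports.

Mueller images travel as 16-plane float32 TIFF stacks (plane k holds
element ``m[k // 4, k % 4]`` in row-major order) accompanied by a JSON
sidecar recording the plane order, normalization, pixel size and
provenance.  Parameter maps are single-plane float32 TIFFs.  Small
matrices can also be read from plain 4x4 CSV files.

Reported numbers are rounded half away from zero (not banker's rounding):
angles to 0.1 degree, dimensionless ratios (D, P_d, modulation) to 0.001.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import MuellerImage, fold_orientation

__all__ = [
    "write_mueller_tiff",
    "read_mueller_tiff",
    "read_mueller_csv",
    "write_map_tiff",
    "read_map_tiff",
    "round_report",
    "roi_summarize",
    "rotation_series_summary",
    "provenance",
]

_ANGLE_DECIMALS = 1
_RATIO_DECIMALS = 3
_ANGLE_KEYS = ("R", "alpha_R", "phase", "phi", "rotation", "delta_alpha")


def round_report(value, decimals: int):
    """Round half away from zero, elementwise.

    ``round_report(0.05, 1) == 0.1`` and ``round_report(-0.05, 1) == -0.1``,
    unlike numpy's round-half-even.
    """
    v = np.asarray(value, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(v) * np.floor(np.abs(v) * factor + 0.5) / factor
    out = np.where(np.isfinite(v), out, v)
    return out if out.ndim else float(out)


def provenance(**extra) -> dict:
    """Provenance stamp embedded in sidecars and reports."""
    import datetime
    import mmphasor

    stamp = {
        "software": "mmphasor",
        "version": mmphasor.__version__,
        "created_utc": datetime.datetime.now(datetime.timezone.utc)
        .isoformat(timespec="seconds"),
    }
    stamp.update(extra)
    return stamp


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_mueller_tiff(path, img: MuellerImage, plane_order: str = "row-major",
                       **extra_meta) -> Path:
    """Write a Mueller image as a 16-plane float32 TIFF plus JSON sidecar.

    Masked pixels are stored as NaN in every plane and restored to the mask
    on reading.  Returns the sidecar path.
    """
    path = Path(path)
    planes = img.to_planes(order=plane_order).astype(np.float32)
    if img.mask is not None:
        planes = planes.copy()
        planes[:, img.mask] = np.nan
    tifffile.imwrite(path, planes, photometric="minisblack")
    meta = {
        "format": "mueller-16plane",
        "plane_order": plane_order,
        "normalized": bool(img.normalized),
        "pixel_size_um": img.pixel_size_um,
        "shape": list(img.shape),
        "meta": _jsonable(img.meta),
        "provenance": provenance(**extra_meta),
    }
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_mueller_tiff(path) -> MuellerImage:
    """Read a 16-plane Mueller TIFF written by :func:`write_mueller_tiff`.

    The JSON sidecar, when present, supplies the plane order and metadata;
    without it row-major order is assumed.  A stack with the wrong number of
    planes is an error, not a guess.  Pixels that are NaN in every plane
    become masked.
    """
    path = Path(path)
    planes = np.asarray(tifffile.imread(path), dtype=float)
    if planes.ndim == 2:
        planes = planes[None]
    if planes.shape[0] != 16:
        raise ValueError(
            f"{path.name}: expected a 16-plane Mueller stack, got "
            f"{planes.shape[0]} plane(s)")
    order = "row-major"
    normalized = False
    pixel_size = None
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        order = info.get("plane_order", order)
        normalized = bool(info.get("normalized", False))
        pixel_size = info.get("pixel_size_um")
        meta = info.get("meta", {}) or {}
        meta["provenance"] = info.get("provenance")
    img = MuellerImage.from_planes(planes, order=order, normalized=normalized,
                                   pixel_size_um=pixel_size, meta=meta)
    mask = np.all(np.isnan(planes), axis=0)
    if np.any(mask):
        img.mask = mask
    return img


def read_mueller_csv(path) -> np.ndarray:
    """Read a single 4x4 Mueller matrix from a CSV file."""
    m = np.loadtxt(Path(path), delimiter=",", dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
    return m


def write_map_tiff(path, data, name: str = "map", **extra_meta) -> Path:
    """Write a single parameter map as float32 TIFF plus JSON sidecar."""
    path = Path(path)
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError("parameter maps must be 2-D")
    tifffile.imwrite(path, arr)
    meta = {"format": "parameter-map", "name": name,
            "shape": list(arr.shape), "provenance": provenance(**extra_meta)}
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_map_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def rotation_series_summary(df: pd.DataFrame, rounded: bool = True) -> dict:
    """Summary statistics of a physical-rotation series table.

    ``df`` holds one row per sample rotation; retardance columns (name
    containing ``R`` but not ``alpha``) are averaged, orientation columns
    (name containing ``alpha``) additionally get the mean of their
    successive differences ``delta_<col>_mean`` — the observed orientation
    step per rotation increment.  Values are rounded half away from zero to
    0.1 degree unless ``rounded=False``.
    """
    if len(df) < 2:
        raise ValueError("a rotation series needs at least two rows")
    out = {}
    for col in df.columns:
        if col == "rotation":
            continue
        vals = np.asarray(df[col], dtype=float)
        out[f"{col}_mean"] = float(np.mean(vals))
        if "alpha" in col:
            out[f"delta_{col}_mean"] = float(np.mean(np.diff(vals)))
    if rounded:
        out = {k: round_report(v, _ANGLE_DECIMALS) for k, v in out.items()}
    return out


def _circular_mean_axis(alpha_deg):
    """Mean and SD of an axis (180-degree periodic) via angle doubling."""
    a = np.radians(2.0 * alpha_deg)
    c, s = np.mean(np.cos(a)), np.mean(np.sin(a))
    mean = fold_orientation(0.5 * math.degrees(math.atan2(s, c)))
    r = min(1.0, math.hypot(c, s))
    # Circular SD of the doubled angle, halved back to axis units.
    sd = 0.5 * math.degrees(math.sqrt(max(0.0, -2.0 * math.log(r)))) if r > 0 else float("inf")
    return mean, sd


def roi_summarize(maps: dict, roi_mask=None, rounded: bool = True) -> pd.DataFrame:
    """Mean +/- SD of each parameter map over an ROI.

    ``maps`` maps parameter names to 2-D arrays.  Orientation-like maps
    (names in {R, alpha_R, ...} treated as angles) get 0.1-degree rounding;
    others 0.001.  ``alpha_R`` additionally gets an axis-aware circular
    mean/SD (angle doubling) alongside the plain arithmetic one.  NaN pixels
    are excluded per map; an ROI with no valid pixels is an error.
    """
    rows = []
    for name, data in maps.items():
        arr = np.asarray(data, dtype=float)
        if roi_mask is not None:
            sel = np.asarray(roi_mask, dtype=bool)
            if sel.shape != arr.shape:
                raise ValueError(f"ROI mask shape does not match map {name!r}")
            vals = arr[sel]
        else:
            vals = arr.ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"empty ROI for map {name!r}: no valid pixels")
        is_angle = any(k in name for k in _ANGLE_KEYS)
        dec = _ANGLE_DECIMALS if is_angle else _RATIO_DECIMALS
        mean = float(np.mean(vals))
        sd = float(np.std(vals))
        row = {"parameter": name, "n": int(vals.size), "mean": mean, "sd": sd}
        if "alpha" in name:
            cmean, csd = _circular_mean_axis(vals)
            row["circular_mean"] = cmean
            row["circular_sd"] = csd
        if rounded:
            for k in ("mean", "sd", "circular_mean", "circular_sd"):
                if k in row and np.isfinite(row[k]):
                    row[k] = round_report(row[k], dec)
        rows.append(row)
    return pd.DataFrame(rows)
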