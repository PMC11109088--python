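"""NIfTI + JSON-sidecar interchange and fixed-format table output.

Volumes travel as NIfTI (RAS+ affine from the voxel spacing) with one JSON
sidecar per series holding the acquisition metadata (b-values, flip angles,
TR in ms, frame times in s, injection frame, relaxivity). Tables are CSV
with a fixed float format so re-running with identical seeds reproduces
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ImageSeries, ParameterMap, ValidationError

__all__ = ["save_series", "load_series", "save_map", "load_map",
           "write_csv", "write_json"]

FLOAT_FORMAT = "%.10g"


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_series(series: ImageSeries, path: "str | Path") -> Path:
    """Write a series as <path>.nii.gz plus <path>.json sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.spacing_mm))
    nii = path.with_suffix(".nii.gz")
    nib.save(img, nii)
    side = {"kind": series.kind, "spacing_mm": list(series.spacing_mm),
            "replicate": series.replicate, "series_id": series.series_id}
    for key, attr in (("b_values_s_mm2", "b_values_s_mm2"),
                      ("flip_angles_deg", "flip_angles_deg"),
                      ("frame_times_s", "frame_times_s")):
        v = getattr(series, attr)
        if v is not None:
            side[key] = np.asarray(v).tolist()
    for key in ("flip_angle_deg", "tr_ms", "injection_frame"):
        v = getattr(series, key)
        if v is not None:
            side[key] = v
    path.with_suffix(".json").write_text(json.dumps(side, indent=1, sort_keys=True))
    return nii


def load_series(path: "str | Path") -> ImageSeries:
    """Read a series written by :func:`save_series` (path with or without
    extension)."""
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in (".json", ".gz", ".nii") else path
    if stem.suffix == ".nii":
        stem = stem.with_suffix("")
    nii = stem.with_suffix(".nii.gz")
    sidecar = stem.with_suffix(".json")
    if not nii.exists() or not sidecar.exists():
        raise ValidationError(f"series {stem} needs both {nii.name} and {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    data = np.asarray(nib.load(str(nii)).dataobj, dtype=float)
    return ImageSeries(
        data=data, kind=meta["kind"],
        spacing_mm=tuple(meta.get("spacing_mm", (1.0, 1.0, 1.0))),
        b_values_s_mm2=meta.get("b_values_s_mm2"),
        flip_angles_deg=meta.get("flip_angles_deg"),
        flip_angle_deg=meta.get("flip_angle_deg"),
        tr_ms=meta.get("tr_ms"),
        frame_times_s=meta.get("frame_times_s"),
        injection_frame=meta.get("injection_frame"),
        replicate=meta.get("replicate", 0),
        series_id=meta.get("series_id", ""))


def save_map(pmap: ParameterMap, path: "str | Path",
             spacing_mm=(1.0, 1.0, 1.0)) -> Path:
    """Write a parameter map (invalid voxels as NaN) with a unit sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(pmap.masked().astype(np.float32), _affine(spacing_mm))
    nii = path.with_suffix(".nii.gz")
    nib.save(img, nii)
    path.with_suffix(".json").write_text(json.dumps(
        {"name": pmap.name, "units": pmap.units}, indent=1, sort_keys=True))
    return nii


def load_map(path: "str | Path") -> ParameterMap:
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in (".json", ".gz", ".nii") else path
    if stem.suffix == ".nii":
        stem = stem.with_suffix("")
    meta = json.loads(stem.with_suffix(".json").read_text())
    values = np.asarray(nib.load(str(stem.with_suffix(".nii.gz"))).dataobj, dtype=float)
    return ParameterMap(values=values, units=meta.get("units", ""),
                        valid=np.isfinite(values), name=meta.get("name", ""))


def write_csv(df: pd.DataFrame, path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_json(obj, path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))
    return path
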