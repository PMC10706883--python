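"""File formats: NIfTI volumes with JSON sidecars, CSV tables, YAML configs.

Every 4D acquisition series is stored as one NIfTI file (4th dimension =
acquisition index) with a JSON sidecar carrying the per-volume acquisition
vectors (inversion time, b-value and direction, echo time, ASL label type
and post-label delay) under BIDS-like key names, plus the voxel geometry
and free-form metadata.  Parameter maps are single 3D NIfTI files with a
sidecar holding units and the map name; masks are uint8 NIfTI.  Clinical
cohorts travel as CSV; configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import AcquisitionSeries, ParameterMap, TissueMasks

__all__ = [
    "save_series", "load_series",
    "save_map", "load_map",
    "save_masks", "load_masks",
    "save_clinical_csv", "load_clinical_csv",
    "save_yaml", "load_yaml",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_series(series: AcquisitionSeries, path: str | Path) -> Path:
    """Write a series as ``<path>.nii.gz`` + ``<path>.json``; returns the NIfTI path."""
    path = Path(path)
    nii_path = path.with_suffix(".nii.gz")
    affine = series.affine
    nib.save(nib.Nifti1Image(series.data.astype(np.float32), affine), nii_path)
    sidecar = {
        "params": _jsonable(series.params),
        "voxel_size_mm": list(series.voxel_size_mm),
        "meta": _jsonable(series.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return nii_path


def load_series(path: str | Path) -> AcquisitionSeries:
    path = Path(path)
    if path.name.endswith(".nii.gz"):
        base = path.with_name(path.name[: -len(".nii.gz")])
    else:
        base = path.with_suffix("")
    img = nib.load(base.with_suffix(".nii.gz"))
    sidecar = json.loads(base.with_suffix(".json").read_text())
    params = {k: np.asarray(v) for k, v in sidecar["params"].items()}
    return AcquisitionSeries(
        data=np.asarray(img.dataobj, dtype=float),
        params=params,
        voxel_size_mm=tuple(sidecar["voxel_size_mm"]),
        meta=sidecar.get("meta", {}),
    )


def save_map(pmap: ParameterMap, path: str | Path) -> Path:
    """Write a parameter map (+status in the sidecar-coded companion file)."""
    path = Path(path)
    nii_path = path.with_suffix(".nii.gz")
    nib.save(nib.Nifti1Image(pmap.data.astype(np.float32), pmap.affine), nii_path)
    sidecar = {
        "name": pmap.name,
        "units": pmap.units,
        "voxel_size_mm": list(pmap.voxel_size_mm),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    if pmap.status is not None:
        status_path = path.parent / (path.stem + "_status")
        nib.save(
            nib.Nifti1Image(pmap.status.astype(np.int16), pmap.affine),
            status_path.with_suffix(".nii.gz"),
        )
    return nii_path


def load_map(path: str | Path) -> ParameterMap:
    path = Path(path)
    if path.name.endswith(".nii.gz"):
        base = path.with_name(path.name[: -len(".nii.gz")])
    else:
        base = path.with_suffix("")
    img = nib.load(base.with_suffix(".nii.gz"))
    sidecar = json.loads(base.with_suffix(".json").read_text())
    status_file = base.parent / (base.name + "_status.nii.gz")
    status = None
    if status_file.exists():
        status = np.asarray(nib.load(status_file).dataobj, dtype=int)
    return ParameterMap(
        data=np.asarray(img.dataobj, dtype=float),
        units=sidecar["units"],
        name=sidecar.get("name", ""),
        status=status,
        voxel_size_mm=tuple(sidecar["voxel_size_mm"]),
    )


def save_masks(masks: TissueMasks, directory: str | Path) -> dict[str, Path]:
    """Write kidney/cortex/medulla as uint8 NIfTI files in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    out = {}
    for name in ("kidney", "cortex", "medulla"):
        p = directory / f"{name}_mask.nii.gz"
        nib.save(nib.Nifti1Image(getattr(masks, name).astype(np.uint8), affine), p)
        out[name] = p
    meta = {"voxel_volume_mm3": masks.voxel_volume_mm3,
            "t1_threshold_ms": masks.t1_threshold_ms}
    (directory / "masks.json").write_text(json.dumps(meta, indent=2))
    return out


def load_masks(directory: str | Path) -> TissueMasks:
    directory = Path(directory)
    meta = json.loads((directory / "masks.json").read_text())
    vols = {
        name: np.asarray(
            nib.load(directory / f"{name}_mask.nii.gz").dataobj) > 0
        for name in ("kidney", "cortex", "medulla")
    }
    return TissueMasks(voxel_volume_mm3=meta["voxel_volume_mm3"],
                       t1_threshold_ms=meta.get("t1_threshold_ms"), **vols)


_CLINICAL_COLUMNS = ["subject_id", "visit_date", "age", "sex", "ethnicity_black",
                     "creatinine_umol_L", "pcr_mg_mmol"]


def save_clinical_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in _CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    table[_CLINICAL_COLUMNS].to_csv(path, index=False)
    return path


def load_clinical_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, parse_dates=["visit_date"])
    missing = [c for c in _CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clinical CSV missing columns: {missing}")
    return table


def save_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_jsonable(obj), sort_keys=False))
    return path


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
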