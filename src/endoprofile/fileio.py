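"""NIfTI / CSV / JSON file formats for all pipeline artefacts.

NIfTI is the canonical volume format (the header carries the voxel size,
preserved to 1e-6 mm on round trip).  A cine stack is one 4D ``.nii.gz``
plus a JSON sidecar with the acquisition protocol; a VFA series is one 3D
volume per flip angle plus a sidecar listing the angles, TR and TE.  Plasma
panels travel as long-format CSV.  Arrays are stored in NIfTI (row, col,
slice[, frame]) order and presented in-memory as (slice, row, col[, frame]).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import CineVolume, VfaSeries
from .protocol import ImagingProtocol
from .t1map import T1Map

__all__ = [
    "protocol_to_dict",
    "protocol_from_dict",
    "save_volume",
    "load_volume",
    "save_cine",
    "load_cine",
    "save_vfa_series",
    "load_vfa_series",
    "save_t1_map",
    "save_panel",
    "load_panel",
    "write_results",
]

_PathLike = Union[str, Path]


def protocol_to_dict(protocol: ImagingProtocol) -> dict:
    return dataclasses.asdict(protocol)


def protocol_from_dict(d: dict) -> ImagingProtocol:
    return ImagingProtocol(
        tr_ms=d["tr_ms"],
        te_ms=d["te_ms"],
        fov_mm=tuple(d["fov_mm"]),
        matrix=tuple(d["matrix"]),
        flip_angles_deg=tuple(d["flip_angles_deg"]),
        n_frames=d.get("n_frames", 1),
        label=d.get("label", ""),
    )


def _affine(voxel_mm: Tuple[float, float, float]) -> np.ndarray:
    return np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])


def save_volume(
    array: np.ndarray, voxel_mm: Tuple[float, float, float], path: _PathLike
) -> Path:
    """Write a (slice, row, col[, frame]) array as NIfTI with voxel size."""
    arr = np.asarray(array)
    if arr.ndim == 3:
        data = np.transpose(arr, (1, 2, 0))
    elif arr.ndim == 4:
        data = np.transpose(arr, (1, 2, 0, 3))
    else:
        raise ValueError("only 3D or 4D volumes are supported")
    img = nib.Nifti1Image(data, _affine(voxel_mm))
    img.header.set_zooms(tuple(voxel_mm) + ((1.0,) if arr.ndim == 4 else ()))
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_volume(path: _PathLike) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    """Read a NIfTI volume back into (slice, row, col[, frame]) order."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: NIfTI header carries no valid voxel size")
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        data = np.transpose(data, (2, 0, 1))
    elif data.ndim == 4:
        data = np.transpose(data, (2, 0, 1, 3))
    else:
        raise ValueError(f"{path}: expected a 3D or 4D volume, got {data.ndim}D")
    return data, tuple(float(z) for z in zooms)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_cine(cine: CineVolume, path: _PathLike) -> Path:
    """Write a cine stack as 4D NIfTI plus a protocol sidecar."""
    path = Path(path)
    save_volume(cine.intensities, cine.voxel_mm, path)
    _sidecar_path(path).write_text(
        json.dumps({"protocol": protocol_to_dict(cine.protocol)}, indent=2)
    )
    return path


def load_cine(path: _PathLike) -> CineVolume:
    path = Path(path)
    data, voxel = load_volume(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing protocol sidecar {sidecar}")
    protocol = protocol_from_dict(json.loads(sidecar.read_text())["protocol"])
    expected = protocol.voxel_mm
    if any(abs(a - b) > 1e-6 for a, b in zip(voxel, expected)):
        raise ValueError(
            f"{path}: header voxel size {voxel} does not match protocol {expected}"
        )
    if data.ndim == 3:
        data = data[..., None]
    return CineVolume(data, protocol, expected)


def save_vfa_series(series: VfaSeries, directory: _PathLike) -> Path:
    """One NIfTI per flip angle plus a ``series.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    voxel = series.protocol.voxel_mm
    files = []
    for i, (alpha, vol) in enumerate(zip(series.flip_angles_deg, series.volumes)):
        name = f"angle_{i:02d}.nii.gz"
        save_volume(vol, voxel, directory / name)
        files.append(name)
    sidecar = {
        "flip_angles_deg": list(series.flip_angles_deg),
        "tr_ms": series.protocol.tr_ms,
        "te_ms": series.protocol.te_ms,
        "files": files,
        "protocol": protocol_to_dict(series.protocol),
    }
    (directory / "series.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_vfa_series(directory: _PathLike) -> VfaSeries:
    directory = Path(directory)
    sidecar_file = directory / "series.json"
    if not sidecar_file.exists():
        raise ValueError(f"missing VFA sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    angles = sidecar["flip_angles_deg"]
    files = sidecar["files"]
    if len(angles) != len(files):
        raise ValueError(
            f"sidecar lists {len(angles)} flip angles for {len(files)} volumes"
        )
    protocol = protocol_from_dict(sidecar["protocol"])
    vols = []
    for name in files:
        data, _ = load_volume(directory / name)
        vols.append(data)
    return VfaSeries(np.stack(vols, axis=0), tuple(angles), protocol)


def save_t1_map(t1_map: T1Map, voxel_mm, directory: _PathLike, stem: str = "t1") -> Path:
    """Write T1 / M0 / fit-quality maps (NaN marks undefined pixels)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {
        f"{stem}_ms.nii.gz": t1_map.t1_ms,
        f"{stem}_m0.nii.gz": t1_map.m0,
        f"{stem}_quality.nii.gz": t1_map.fit_quality,
    }
    for name, arr in arrays.items():
        vol = arr if arr.ndim == 3 else arr[None, ...]
        save_volume(vol.astype(np.float64), voxel_mm, directory / name)
    return directory


_PANEL_COLUMNS = ["animal_id", "group", "analyte", "concentration", "units"]


def save_panel(panel: pd.DataFrame, path: _PathLike) -> Path:
    missing = [c for c in _PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing columns: {missing}")
    path = Path(path)
    panel[_PANEL_COLUMNS].to_csv(path, index=False)
    return path


def load_panel(path: _PathLike) -> pd.DataFrame:
    panel = pd.read_csv(path)
    missing = [c for c in _PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"{path} is missing columns: {missing}")
    inconsistent = (
        panel.groupby("analyte")["units"].nunique(dropna=False).loc[lambda s: s > 1]
    )
    if len(inconsistent):
        raise ValueError(
            f"inconsistent units for analytes: {list(inconsistent.index)}"
        )
    if (panel["concentration"] < 0).any():
        raise ValueError("concentrations must be non-negative")
    return panel


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_results(results: dict, path: _PathLike) -> Path:
    """Write a results dictionary as deterministic, sorted-key JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(results), indent=2, sort_keys=True))
    return path
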