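"""Readers and writers: NIfTI volumes, YAML protocols, CSV tables.

Volumes are stored as NIfTI-1 with voxel spacing in the header zooms and
float32 data (MR-typical); all fitting runs in float64 internally.
Calibration points travel as CSV with header
``level,unit,r1_mean,r1_sd,n_voxels``; depth profiles as
``depth_mm,value,value_sd``; ionization-chamber references as
``depth_mm,relative_dose``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationPoint
from .dose_analysis import DepthProfile
from .relaxometry import ScanProtocol

__all__ = [
    "read_volume",
    "write_volume",
    "read_protocol_yaml",
    "write_protocol_yaml",
    "read_calibration_csv",
    "write_calibration_csv",
    "read_reference_pdd_csv",
    "read_profile_csv",
    "write_profile_csv",
    "write_json_report",
]


def read_volume(path):
    """Load a 3D NIfTI volume; returns (float64 array, spacing mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_volume(volume, spacing_mm, path):
    """Write a 3D volume as float32 NIfTI-1 with the given voxel spacing."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.header.set_zooms(tuple(float(s) for s in spacing_mm))
    nib.save(img, str(path))


# YAML protocol block mirrors the acquisition-table field names.
_PROTOCOL_KEYS = {
    "tr_ms": "tr_ms",
    "te_ms": "te_ms",
    "fa_deg": "flip_angles_deg",
    "fov_mm": "fov_mm",
    "matrix": "matrix",
    "st_mm": "slice_thickness_mm",
    "ns": "n_slices",
    "bw": "bandwidth_hz_px",
    "nex": "nex",
}


def protocol_to_dict(protocol: ScanProtocol) -> dict:
    return {
        "tr_ms": protocol.tr_ms,
        "te_ms": protocol.te_ms,
        "fa_deg": list(protocol.flip_angles_deg),
        "fov_mm": list(protocol.fov_mm),
        "matrix": list(protocol.matrix),
        "st_mm": protocol.slice_thickness_mm,
        "ns": protocol.n_slices,
        "bw": protocol.bandwidth_hz_px,
        "nex": protocol.nex,
    }


def protocol_from_dict(block: dict) -> ScanProtocol:
    kwargs = {}
    for key, attr in _PROTOCOL_KEYS.items():
        if key in block:
            v = block[key]
            kwargs[attr] = tuple(v) if isinstance(v, (list, tuple)) else v
    return ScanProtocol(**kwargs)


def read_protocol_yaml(path) -> ScanProtocol:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"protocol file not found: {path}")
    with open(path) as fh:
        block = yaml.safe_load(fh)
    if not isinstance(block, dict):
        raise ValueError(f"{path}: expected a YAML mapping of protocol fields")
    return protocol_from_dict(block.get("protocol", block))


def write_protocol_yaml(protocol: ScanProtocol, path):
    with open(path, "w") as fh:
        yaml.safe_dump({"protocol": protocol_to_dict(protocol)}, fh, sort_keys=False)


def read_calibration_csv(path) -> list[CalibrationPoint]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"calibration file not found: {path}")
    df = pd.read_csv(path)
    for col in ("level", "r1_mean"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    points = []
    for _, row in df.iterrows():
        n = row.get("n_voxels")
        points.append(
            CalibrationPoint(
                level=float(row["level"]),
                r1_mean=float(row["r1_mean"]),
                r1_sd=float(row.get("r1_sd", 0.0) or 0.0),
                n_voxels=int(n) if n == n and n is not None else None,
            )
        )
    return points


def write_calibration_csv(points: list[CalibrationPoint], path, unit: str = "mM"):
    pd.DataFrame(
        [
            {
                "level": p.level,
                "unit": unit,
                "r1_mean": p.r1_mean,
                "r1_sd": p.r1_sd,
                "n_voxels": p.n_voxels,
            }
            for p in points
        ]
    ).to_csv(path, index=False)


def read_reference_pdd_csv(path) -> DepthProfile:
    """Ionization-chamber depth-dose reference (depth_mm, relative_dose)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference PDD file not found: {path}")
    df = pd.read_csv(path)
    for col in ("depth_mm", "relative_dose"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    df = df.sort_values("depth_mm")
    return DepthProfile(
        depth_mm=df["depth_mm"].to_numpy(float),
        value=df["relative_dose"].to_numpy(float),
    )


def read_profile_csv(path) -> DepthProfile:
    df = pd.read_csv(path)
    sd = df["value_sd"].to_numpy(float) if "value_sd" in df.columns else None
    return DepthProfile(
        depth_mm=df["depth_mm"].to_numpy(float),
        value=df["value"].to_numpy(float),
        value_sd=sd,
    )


def write_profile_csv(profile: DepthProfile, path):
    df = pd.DataFrame({"depth_mm": profile.depth_mm, "value": profile.value})
    if profile.value_sd is not None:
        df["value_sd"] = profile.value_sd
    df.to_csv(path, index=False)


def write_json_report(report: dict, path):
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
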