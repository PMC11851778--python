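"""NIfTI-1 readers/writers and JSON sidecar helpers.

Volumes travel as NIfTI-1 with an axis-aligned affine built from the voxel
size; echo times and sequence parameters live in JSON sidecars because NIfTI
has no standard fields for them. Round trips preserve data to float32
precision, voxel sizes and axis order.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume", "read_json", "write_json"]


def write_volume(data: np.ndarray, voxel_size_mm, path) -> Path:
    """Write a 3D/4D array as NIfTI-1 (float32, or the integer dtype given)."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise ValueError("only 3D and 4D volumes are supported")
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(voxel_size_mm) + ((1.0,) if data.ndim == 4 else ()))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_volume(path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a NIfTI-1 volume; returns ``(data, voxel_size_mm)``."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise OSError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise OSError(f"{path}: expected a 3D or 4D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
    return path


def read_json(path):
    return json.loads(Path(path).read_text())


def _default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
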