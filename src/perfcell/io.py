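"""Thin NIfTI / JSON / text-matrix I/O helpers shared by the pipeline stages."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "affine_from_voxel_size",
    "load_volume",
    "save_volume",
    "load_json",
    "save_json",
    "save_matrix_txt",
    "load_matrix_txt",
]


def affine_from_voxel_size(voxel_size) -> np.ndarray:
    """Axis-aligned NIfTI affine with the given voxel size (mm), origin at 0."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume, returning (float64 data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    return path


def save_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))
    return path


def load_json(path):
    return json.loads(Path(path).read_text())


def save_matrix_txt(matrix: np.ndarray, path) -> Path:
    """Save a 4x4 world-coordinate transform as a plain-text row-major matrix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(matrix, dtype=np.float64), fmt="%.12g")
    return path


def load_matrix_txt(path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}, got shape {m.shape}")
    return m
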