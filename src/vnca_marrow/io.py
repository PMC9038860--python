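"""NIfTI input/output for volumes and label maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .spectral import SpectralVolume, VNCaVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_spectral",
    "read_label_map",
    "write_label_map",
]


def write_volume(
    data: np.ndarray, spacing_mm: tuple[float, float, float], path: str | Path
) -> None:
    """Write a 3-D grid as NIfTI-1 with an RAS diagonal affine."""
    affine = np.diag([*spacing_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a 3-D NIfTI volume, returning the array and voxel spacing in mm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D data, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    return data, spacing  # type: ignore[return-value]


def read_spectral(
    conventional: str | Path, low: str | Path, high: str | Path
) -> SpectralVolume:
    """Load co-registered conventional/low/high volumes, checking geometry."""
    conv, sp = read_volume(conventional)
    lo, sp_l = read_volume(low)
    hi, sp_h = read_volume(high)
    for path, arr, s in ((low, lo, sp_l), (high, hi, sp_h)):
        if arr.shape != conv.shape:
            raise ValueError(
                f"shape mismatch between {conventional} {conv.shape} and {path} {arr.shape}"
            )
        if not np.allclose(s, sp):
            raise ValueError(f"spacing mismatch between {conventional} and {path}")
    return SpectralVolume(conventional=conv, low=lo, high=hi, spacing_mm=sp)


def read_vnca(path: str | Path, suppression_index: float = 25.0) -> VNCaVolume:
    data, spacing = read_volume(path)
    return VNCaVolume(vnca=data, spacing_mm=spacing, suppression_index=suppression_index)


def write_label_map(
    labels: np.ndarray, spacing_mm: tuple[float, float, float], path: str | Path
) -> None:
    affine = np.diag([*spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), str(path))


def read_label_map(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    data, spacing = read_volume(path)
    labels = np.asarray(data)
    if not np.allclose(labels, np.round(labels)):
        raise ValueError(f"{path}: label map must be integer-valued")
    return labels.astype(np.int32), spacing
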