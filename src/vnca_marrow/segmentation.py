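"""Marrow volume-of-interest construction.

Stages: (1) vertebra labelling — either a rule-based labeller suited to the
synthetic phantoms (bone threshold, interior fill, split of fused bodies at
axial-profile minima) or an externally produced integer label map; (2)
bottom-up selection of the 17 most caudal vertebrae; (3) morphological
erosion by a 3 mm ball, honouring anisotropic voxel spacing, to exclude the
cortical shell which carries no marrow.  Segmentations are never silently
corrected: miscounts surface as errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .spectral import VNCaVolume

__all__ = [
    "LabeledSpine",
    "VOIMask",
    "label_vertebrae",
    "labeled_spine_from_map",
    "select_bottom_k",
    "erode_cortex",
    "extract_voxels",
    "ball_structuring_element",
]

DEFAULT_BONE_THRESHOLD_HU = 200.0
DEFAULT_VERTEBRA_COUNT = 17
DEFAULT_EROSION_MM = 3.0

#: array axis taken as inferior-superior when no orientation metadata exists
IS_AXIS = 2


@dataclass
class LabeledSpine:
    """Integer vertebra labels plus their caudal-to-cranial ordering."""

    label_map: np.ndarray
    spacing_mm: tuple[float, float, float]
    ordering: list[int]

    def __post_init__(self) -> None:
        present = set(np.unique(self.label_map)) - {0}
        if any(lab < 0 for lab in present):
            raise ValueError("vertebra labels must be positive")
        if set(self.ordering) != present:
            raise ValueError("ordering must be a permutation of the present labels")

    @property
    def n_vertebrae(self) -> int:
        return len(self.ordering)


@dataclass
class VOIMask:
    """Boolean volume-of-interest with physical spacing."""

    mask: np.ndarray
    spacing_mm: tuple[float, float, float]

    @property
    def volume_cm3(self) -> float:
        voxel_mm3 = float(np.prod(self.spacing_mm))
        return float(self.mask.sum()) * voxel_mm3 / 1000.0


def labeled_spine_from_map(
    label_map: np.ndarray, spacing_mm: tuple[float, float, float]
) -> LabeledSpine:
    """Wrap an external (or ground-truth) label map; lesion voxels (-1) drop out."""
    labels = np.where(label_map > 0, label_map, 0).astype(np.int32)
    return LabeledSpine(label_map=labels, spacing_mm=spacing_mm, ordering=_order_caudal(labels))


def _order_caudal(labels: np.ndarray, axis: int = IS_AXIS) -> list[int]:
    present = [int(v) for v in np.unique(labels) if v > 0]
    centroids = ndimage.center_of_mass(labels > 0, labels, present)
    return [lab for _, lab in sorted(zip((c[axis] for c in centroids), present))]


def _split_fused(component: np.ndarray, axis: int = IS_AXIS) -> list[np.ndarray]:
    """Split a component at deep minima of its axial cross-section profile."""
    sum_axes = tuple(a for a in range(component.ndim) if a != axis)
    profile = component.sum(axis=sum_axes).astype(float)
    occupied = np.nonzero(profile)[0]
    lo, hi = occupied[0], occupied[-1]
    inner = profile[lo : hi + 1]
    peak = inner.max()
    valleys, _ = find_peaks(peak - inner, prominence=0.5 * peak)
    valleys = [v for v in valleys if inner[v] < 0.5 * peak]
    if not valleys:
        return [component]
    cuts = [lo - 1] + [lo + v for v in valleys] + [hi + 1]
    parts = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        slab = np.zeros_like(component)
        idx = [slice(None)] * component.ndim
        idx[axis] = slice(a + 1, b + 1)
        slab[tuple(idx)] = component[tuple(idx)]
        if slab.any():
            parts.append(slab)
    return parts


def label_vertebrae(
    conventional: np.ndarray,
    spacing_mm: tuple[float, float, float],
    bone_threshold: float = DEFAULT_BONE_THRESHOLD_HU,
    min_body_volume_cm3: float = 1.0,
) -> LabeledSpine:
    """Rule-based vertebra labelling of a phantom-like conventional volume.

    Voxels above the bone threshold seed connected components, each
    component's interior is filled (the cortical shell is a closed surface),
    merged bodies are split at axial-profile minima, and the resulting bodies
    are labelled caudal to cranial.  Components smaller than
    ``min_body_volume_cm3`` are noise speckle, not vertebrae, and are dropped.
    """
    if conventional.size == 0:
        raise ValueError("empty volume")
    bone = conventional > bone_threshold
    comp, n = ndimage.label(bone)
    if n == 0:
        raise ValueError("no spine found above the bone threshold")
    min_voxels = min_body_volume_cm3 * 1000.0 / float(np.prod(spacing_mm))

    bodies: list[np.ndarray] = []
    for obj_idx, sl in enumerate(ndimage.find_objects(comp), start=1):
        sub = comp[sl] == obj_idx
        if sub.sum() < min_voxels:
            continue
        filled = ndimage.binary_fill_holes(sub)
        full = np.zeros(conventional.shape, dtype=bool)
        full[sl] = filled
        bodies.extend(b for b in _split_fused(full) if b.sum() >= min_voxels)
    if not bodies:
        raise ValueError("no spine found above the bone threshold")

    labels = np.zeros(conventional.shape, dtype=np.int32)
    order = sorted(
        range(len(bodies)), key=lambda i: ndimage.center_of_mass(bodies[i])[IS_AXIS]
    )
    for new_label, i in enumerate(order, start=1):
        labels[bodies[i]] = new_label
    return LabeledSpine(
        label_map=labels, spacing_mm=spacing_mm, ordering=list(range(1, len(bodies) + 1))
    )


def select_bottom_k(ls: LabeledSpine, k: int = DEFAULT_VERTEBRA_COUNT) -> VOIMask:
    """Union of the ``k`` most caudal vertebrae (counting from the bottom up)."""
    if ls.n_vertebrae < k:
        raise ValueError(f"found {ls.n_vertebrae} < {k} vertebrae")
    keep = set(ls.ordering[:k])
    mask = np.isin(ls.label_map, list(keep))
    return VOIMask(mask=mask, spacing_mm=ls.spacing_mm)


def ball_structuring_element(
    radius_mm: float, spacing_mm: tuple[float, float, float]
) -> np.ndarray:
    """Discrete ball of physical radius on an anisotropic voxel lattice."""
    half = [int(np.floor(radius_mm / s + 1e-9)) for s in spacing_mm]
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    dist2 = sum((g * s / radius_mm) ** 2 for g, s in zip(grids, spacing_mm))
    return dist2 <= 1.0 + 1e-9


def erode_cortex(m: VOIMask, radius_mm: float = DEFAULT_EROSION_MM) -> VOIMask:
    """Erode the VOI by a physical-radius ball to strip bordering cortex."""
    if radius_mm < 0:
        raise ValueError("erosion radius must be non-negative")
    if radius_mm == 0:
        return VOIMask(mask=m.mask.copy(), spacing_mm=m.spacing_mm)
    selem = ball_structuring_element(radius_mm, m.spacing_mm)
    eroded = ndimage.binary_erosion(m.mask, structure=selem, border_value=0)
    if not eroded.any() and m.mask.any():
        warnings.warn(
            f"erosion by {radius_mm} mm removed the entire VOI", stacklevel=2
        )
    return VOIMask(mask=eroded, spacing_mm=m.spacing_mm)


def extract_voxels(v: VNCaVolume | np.ndarray, m: VOIMask) -> tuple[np.ndarray, float]:
    """HU values inside the mask plus the mask volume in cm^3."""
    grid = v.vnca if isinstance(v, VNCaVolume) else np.asarray(v)
    if grid.shape != m.mask.shape:
        raise ValueError(f"shape mismatch: volume {grid.shape} vs mask {m.mask.shape}")
    return grid[m.mask], m.volume_cm3
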