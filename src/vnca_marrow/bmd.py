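"""Phantom-less (in-body calibrated) trabecular bone mineral density.

Quantitative CT without a calibration phantom uses two internal reference
tissues — subcutaneous fat and paravertebral muscle — to pin an affine map
from conventional HU to hydroxyapatite-equivalent density.  Because both
references ride along with any scanner offset, the calibration cancels
global drift.  Trabecular density is read from the eroded interiors of the
first to third lumbar vertebrae; vertebrae hit by an osteolytic lesion are
excluded and measurement shifts caudally ("extended to the lower spine").

The reference equivalent densities default to values derived from the
synthetic material basis and the uninfiltrated marrow composition, so that
on noise-free phantoms the measurement recovers the generating density
exactly.  They are package conventions, configurable like any other
calibration constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .segmentation import LabeledSpine, ball_structuring_element
from .spectral import DEFAULT_BASIS, MaterialBasis

__all__ = [
    "CalibrationPair",
    "LinearCalibration",
    "BMDResult",
    "derive_calibration_pair",
    "internal_calibration",
    "measure_bmd",
    "roi_mean",
    "DEFAULT_TARGET_POSITIONS",
]

#: caudal-ordering positions of L3, L2, L1 when 17 vertebrae are counted
#: upward from L5 (positions 1 and 2 are L5/L4, kept free as fallback)
DEFAULT_TARGET_POSITIONS = (3, 4, 5)
DEFAULT_ROI_EROSION_MM = 3.0


@dataclass(frozen=True)
class CalibrationPair:
    """Reference HU and equivalent densities of the two calibration tissues."""

    hu_fat_ref: float
    hu_muscle_ref: float
    density_fat_equiv: float
    density_muscle_equiv: float

    def __post_init__(self) -> None:
        if not self.hu_muscle_ref > self.hu_fat_ref:
            raise ValueError("muscle reference HU must exceed fat reference HU")
        if self.density_fat_equiv == self.density_muscle_equiv:
            raise ValueError("reference equivalent densities must differ")


def derive_calibration_pair(
    basis: MaterialBasis = DEFAULT_BASIS, base_soft_fraction: float = 0.05
) -> CalibrationPair:
    """Reference densities consistent with the forward model.

    Mineral replaces fat at ``(hu_mineral - hu_fat) / reference_density`` HU
    per mg/ml on the conventional image, and uninfiltrated mineral-free
    marrow sits at the fat/soft blend HU.  Anchoring the fat and muscle
    reference HU on that line makes the two-point calibration invert the
    forward model exactly at zero infiltration.
    """
    slope = (basis.hu_mineral_conv - basis.hu_fat_conv) / basis.reference_mineral_density
    hu_base = (1.0 - base_soft_fraction) * basis.hu_fat_conv + base_soft_fraction * basis.hu_soft_conv
    return CalibrationPair(
        hu_fat_ref=basis.hu_fat_conv,
        hu_muscle_ref=basis.hu_soft_conv,
        density_fat_equiv=(basis.hu_fat_conv - hu_base) / slope,
        density_muscle_equiv=(basis.hu_soft_conv - hu_base) / slope,
    )


DEFAULT_CALIBRATION_PAIR = derive_calibration_pair()


@dataclass(frozen=True)
class LinearCalibration:
    """Affine HU -> mg/ml map through the two measured reference ROIs."""

    slope: float  # mg/ml per HU
    intercept: float

    def __call__(self, hu: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(hu, dtype=float)


@dataclass
class BMDResult:
    bmd_mg_ml: float
    vertebrae_used: list[int]
    fallback_used: bool


def internal_calibration(
    muscle_roi_mean: float,
    fat_roi_mean: float,
    pair: CalibrationPair = DEFAULT_CALIBRATION_PAIR,
) -> LinearCalibration:
    """Two-point line through the measured fat and muscle ROI means."""
    if muscle_roi_mean <= fat_roi_mean:
        raise ValueError(
            f"degenerate calibration: muscle ROI mean {muscle_roi_mean} must "
            f"exceed fat ROI mean {fat_roi_mean}"
        )
    slope = (pair.density_muscle_equiv - pair.density_fat_equiv) / (
        muscle_roi_mean - fat_roi_mean
    )
    intercept = pair.density_fat_equiv - slope * fat_roi_mean
    return LinearCalibration(slope=slope, intercept=intercept)


def roi_mean(
    volume: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator | None = None,
    subsample: float = 1.0,
) -> float:
    """Mean HU over an ROI; optional random subsampling emulates reader-specific
    ROI placement when repeated measurements are simulated."""
    values = volume[mask]
    if values.size == 0:
        raise ValueError("empty ROI")
    if rng is not None and subsample < 1.0:
        keep = max(1, int(round(values.size * subsample)))
        values = rng.choice(values, size=keep, replace=False)
    return float(values.mean())


def _intersects_lesion(vert_mask: np.ndarray, lesion_mask: np.ndarray | None) -> bool:
    if lesion_mask is None or not lesion_mask.any():
        return False
    filled = ndimage.binary_fill_holes(vert_mask)
    return bool(np.any(filled & lesion_mask))


def measure_bmd(
    conventional: np.ndarray,
    ls: LabeledSpine,
    cal: LinearCalibration,
    target_positions: Sequence[int] = DEFAULT_TARGET_POSITIONS,
    lesion_mask: np.ndarray | None = None,
    erosion_mm: float = DEFAULT_ROI_EROSION_MM,
    rng: np.random.Generator | None = None,
    subsample: float = 1.0,
) -> BMDResult:
    """Trabecular BMD from the eroded interiors of the target vertebrae.

    ``target_positions`` index the caudal ordering (1 = most caudal).  A
    target intersecting the lesion mask is dropped and, where possible,
    replaced by the next more caudal unused vertebra.
    """
    missing = [p for p in target_positions if p < 1 or p > ls.n_vertebrae]
    if missing:
        raise ValueError(f"target positions {missing} outside the labelled spine")

    chosen: list[int] = []
    fallback_used = False
    pool = [p for p in range(min(target_positions) - 1, 0, -1)]  # caudal fallbacks
    for pos in target_positions:
        label = ls.ordering[pos - 1]
        if _intersects_lesion(ls.label_map == label, lesion_mask):
            fallback_used = True
            while pool:
                alt = pool.pop(0)
                alt_label = ls.ordering[alt - 1]
                if not _intersects_lesion(ls.label_map == alt_label, lesion_mask):
                    chosen.append(alt_label)
                    break
        else:
            chosen.append(label)

    values = []
    used = []
    selem = ball_structuring_element(erosion_mm, ls.spacing_mm) if erosion_mm > 0 else None
    for label in chosen:
        vert = ls.label_map == label
        roi = vert if selem is None else ndimage.binary_erosion(vert, selem, border_value=0)
        if lesion_mask is not None:
            roi = roi & ~lesion_mask
        if roi.any():
            values.append(conventional[roi])
            used.append(label)
    if not values:
        raise ValueError("no measurable vertebra for BMD")
    sample = np.concatenate(values)
    if rng is not None and subsample < 1.0:
        keep = max(1, int(round(sample.size * subsample)))
        sample = rng.choice(sample, size=keep, replace=False)
    return BMDResult(
        bmd_mg_ml=float(cal(sample.mean())),
        vertebrae_used=used,
        fallback_used=fallback_used,
    )
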