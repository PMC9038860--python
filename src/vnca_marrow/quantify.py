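"""Attenuation histograms and the non-fatty portion of bone marrow.

After calcium suppression a marrow voxel's attenuation reflects only its
fat/soft-tissue blend, so the share of voxels above 0 HU measures how much
fatty marrow has been displaced by cellular infiltrate.  The headline
statistic is

    non-fatty portion (%) = 100 * |{HU > 0}| / |{HU > -1000}|

with strict inequalities on both sides: voxels at or below -1000 HU are
calcium-removal artefacts of densely calcified structures, not marrow, and
are excluded from the denominator.  Histograms (5 HU bins over
[-1024, +3071)) are standardised to a common VOI volume of 336.0 cm^3 so
that cohort-level plots cover the same area; the statistic itself is always
computed from the raw voxel sample to avoid quantisation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HistogramSpec",
    "AttenuationHistogram",
    "MarrowStatistic",
    "attenuation_histogram",
    "standardize_histogram",
    "non_fatty_portion",
]

NON_FATTY_THRESHOLD_HU = 0.0
MARROW_FLOOR_HU = -1000.0


@dataclass(frozen=True)
class HistogramSpec:
    lower_edge: float = -1024.0
    upper_edge: float = 3071.0
    bin_width: float = 5.0
    standard_volume_cm3: float = 336.0

    def __post_init__(self) -> None:
        span = self.upper_edge - self.lower_edge
        if span <= 0 or self.bin_width <= 0:
            raise ValueError("histogram range and bin width must be positive")
        n = span / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("histogram range must be divisible by the bin width")

    @property
    def n_bins(self) -> int:
        return round((self.upper_edge - self.lower_edge) / self.bin_width)

    @property
    def edges(self) -> np.ndarray:
        return self.lower_edge + self.bin_width * np.arange(self.n_bins + 1)


@dataclass
class AttenuationHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    voi_volume_cm3: float
    out_of_range: int = 0
    standardized_counts: np.ndarray | None = field(default=None)


@dataclass(frozen=True)
class MarrowStatistic:
    """Non-fatty portion of the marrow VOI plus its raw ingredients."""

    non_fatty_percent: float
    n_above_zero: int
    n_marrow: int
    voi_volume_cm3: float


def attenuation_histogram(
    sample: np.ndarray, spec: HistogramSpec = HistogramSpec(), voi_volume_cm3: float = 0.0
) -> AttenuationHistogram:
    """Bin a VNCa voxel sample into left-closed, right-open 5 HU bins.

    Values outside [lower, upper) are excluded from the counts and reported
    in the out-of-range tally, so ``sum(counts) + out_of_range == len(sample)``.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size and not np.all(np.isfinite(sample)):
        raise ValueError("sample contains non-finite values")
    in_range = (sample >= spec.lower_edge) & (sample < spec.upper_edge)
    idx = np.floor((sample[in_range] - spec.lower_edge) / spec.bin_width).astype(int)
    counts = np.bincount(idx, minlength=spec.n_bins)
    return AttenuationHistogram(
        bin_edges=spec.edges,
        counts=counts,
        voi_volume_cm3=voi_volume_cm3,
        out_of_range=int(sample.size - in_range.sum()),
    )


def standardize_histogram(
    h: AttenuationHistogram, spec: HistogramSpec = HistogramSpec()
) -> AttenuationHistogram:
    """Scale counts to the standard VOI volume so cohort plots share an area."""
    if h.voi_volume_cm3 <= 0:
        raise ValueError("VOI volume must be positive for standardization")
    factor = spec.standard_volume_cm3 / h.voi_volume_cm3
    return AttenuationHistogram(
        bin_edges=h.bin_edges,
        counts=h.counts,
        voi_volume_cm3=h.voi_volume_cm3,
        out_of_range=h.out_of_range,
        standardized_counts=h.counts * factor,
    )


def non_fatty_portion(sample: np.ndarray, voi_volume_cm3: float = 0.0) -> MarrowStatistic:
    """Percentage of marrow voxels (> -1000 HU) with attenuation > 0 HU."""
    sample = np.asarray(sample, dtype=float).ravel()
    n_marrow = int(np.count_nonzero(sample > MARROW_FLOOR_HU))
    if n_marrow == 0:
        raise ValueError("no marrow voxels above -1000 HU")
    n_above = int(np.count_nonzero(sample > NON_FATTY_THRESHOLD_HU))
    return MarrowStatistic(
        non_fatty_percent=100.0 * n_above / n_marrow,
        n_above_zero=n_above,
        n_marrow=n_marrow,
        voi_volume_cm3=voi_volume_cm3,
    )
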