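"""Synthetic dual-energy spine phantoms with known marrow composition.

The phantom emulates the imaging situation of a thoracolumbar whole-body CT
in plasma-cell disorders: a stack of cortical-shelled vertebral bodies whose
marrow interior mixes fat, soft tissue and bone mineral.  Marrow infiltration
by plasma cells displaces fatty marrow, so the soft-tissue fraction rises
linearly with the infiltration fraction.  Focal osteolytic lesions replace
bone with soft-dominant, mineral-free tissue.  Two reference-tissue rods
(subcutaneous fat, paravertebral muscle) run alongside the spine so that
phantom-less in-body BMD calibration can be exercised.

Vertebral bodies are plain cylinders with flat endplates: the quantity under
study is marrow-interior attenuation, not anatomy.  Cohort sampling emulates
a mixed myeloma/MGUS population (myeloma infiltration spread over a wide
range, MGUS at zero) with per-patient ground truth for every downstream stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .spectral import (
    DEFAULT_BASIS,
    CompartmentFractions,
    MaterialBasis,
    SpectralVolume,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "DEFAULT_PHANTOM_SPEC",
    "infiltration_to_fractions",
    "build_phantom",
    "sample_cohort",
    "vertebra_centers_mm",
]

AIR_HU = -1000.0

#: composition of the cortical shell (mineral-dominant)
CORTICAL_FRACTIONS = CompartmentFractions(fat=0.01, soft=0.01, mineral=0.98)
#: composition written into osteolytic lesions (bone destroyed, soft-dominant)
LESION_FRACTIONS = CompartmentFractions(fat=0.2, soft=0.8, mineral=0.0)
#: probability that a reader's lesion call matches ground truth
READER_ACCURACY = 0.9


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, composition and acquisition parameters of one phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 344)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    n_vertebrae: int = 18
    body_radius_mm: float = 16.0
    body_height_mm: float = 24.0
    gap_mm: float = 4.0
    cortical_thickness_mm: float = 2.0
    infiltration: float = 0.0
    base_soft_fraction: float = 0.05
    infiltration_gain: float = 0.6
    marrow_mineral_fraction: float | None = None  # None: derived from true_bmd
    true_bmd_mg_ml: float = 96.8
    lesions: tuple[tuple[tuple[float, float, float], float], ...] = ()
    noise_sd_hu: float = 15.0
    cortical_bh_deficit_hu: float = 30.0
    reference_rod_radius_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise ValueError("need at least one vertebra")
        for name in ("body_radius_mm", "body_height_mm", "gap_mm", "cortical_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.infiltration <= 1.0:
            raise ValueError("infiltration must lie in [0, 1]")
        if self.infiltration_gain + self.base_soft_fraction > 1.0:
            raise ValueError("soft fraction would exceed 1 at full infiltration")
        if self.noise_sd_hu < 0:
            raise ValueError("noise sd must be non-negative")

    def mineral_fraction(self, basis: MaterialBasis = DEFAULT_BASIS) -> float:
        if self.marrow_mineral_fraction is not None:
            return self.marrow_mineral_fraction
        return self.true_bmd_mg_ml / basis.reference_mineral_density


DEFAULT_PHANTOM_SPEC = PhantomSpec()


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    label_map: np.ndarray  # 0 background, 1..n caudal->cranial, -1 lesion
    fraction_map: np.ndarray  # (..., 3) fat/soft/mineral, defined where label != 0
    true_infiltration: float
    true_bmd: float
    spacing_mm: tuple[float, float, float]
    cortical_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    fat_ref_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    muscle_ref_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def infiltration_to_fractions(
    i: float, spec: PhantomSpec, basis: MaterialBasis = DEFAULT_BASIS
) -> CompartmentFractions:
    """Marrow composition at infiltration ``i``: soft tissue displaces fat.

    ``soft = base + gain * i`` with the mineral fraction fixed; fat takes the
    remainder.  Raises if the configuration pushes any fraction out of [0, 1].
    """
    if not 0.0 <= i <= 1.0:
        raise ValueError("infiltration must lie in [0, 1]")
    soft = spec.base_soft_fraction + spec.infiltration_gain * i
    mineral = spec.mineral_fraction(basis)
    fat = 1.0 - soft - mineral
    if not (0.0 <= soft <= 1.0 and 0.0 <= mineral <= 1.0 and 0.0 <= fat <= 1.0):
        raise ValueError(
            f"configuration error: fractions (fat={fat:.3f}, soft={soft:.3f}, "
            f"mineral={mineral:.3f}) leave [0, 1] at infiltration {i}"
        )
    return CompartmentFractions(fat=fat, soft=soft, mineral=mineral)


def vertebra_centers_mm(spec: PhantomSpec) -> list[tuple[float, float, float]]:
    """Centre of each vertebral body, caudal to cranial, in mm."""
    nx, ny, _ = spec.grid_shape
    sx, sy, _ = spec.spacing_mm
    cx, cy = nx * sx / 2.0, ny * sy / 2.0
    pitch = spec.body_height_mm + spec.gap_mm
    return [
        (cx, cy, spec.gap_mm + (v - 0.5) * pitch) for v in range(1, spec.n_vertebrae + 1)
    ]


def _coords_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(
        (np.arange(n) + 0.5) * s for n, s in zip(spec.grid_shape, spec.spacing_mm)
    )  # type: ignore[return-value]


def build_phantom(
    spec: PhantomSpec, basis: MaterialBasis = DEFAULT_BASIS
) -> tuple[SpectralVolume, PhantomTruth]:
    """Generate the dual-energy volume and its ground truth.

    Attenuation is the linear three-compartment mixture at each energy plus
    independent additive Gaussian noise.  The cortical shell's conventional
    image receives a small beam-hardening deficit relative to the linear
    mixture prediction, which the calcium-suppression algebra amplifies into
    the far-negative VNCa values characteristic of dense bone.  Identical
    seeds give bit-identical volumes.
    """
    nx, ny, nz = spec.grid_shape
    x, y, z = _coords_mm(spec)
    cx, cy = nx * spec.spacing_mm[0] / 2.0, ny * spec.spacing_mm[1] / 2.0
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2  # (nx, ny)

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    fractions = np.zeros(spec.grid_shape + (3,), dtype=float)
    cortical = np.zeros(spec.grid_shape, dtype=bool)

    pitch = spec.body_height_mm + spec.gap_mm
    z_extent = nz * spec.spacing_mm[2]
    half_h = spec.body_height_mm / 2.0
    t = spec.cortical_thickness_mm
    marrow_frac = infiltration_to_fractions(spec.infiltration, spec, basis)
    in_radius = r2 <= spec.body_radius_mm**2
    marrow_radius = (spec.body_radius_mm - t) ** 2

    for v in range(1, spec.n_vertebrae + 1):
        zc = spec.gap_mm + (v - 0.5) * pitch
        if zc + half_h > z_extent or (cx + spec.body_radius_mm) > nx * spec.spacing_mm[0]:
            raise ValueError(f"vertebra {v} exceeds the phantom grid")
        zsel = np.abs(z - zc) <= half_h
        body = in_radius[:, :, None] & zsel[None, None, :]
        interior = (r2 <= marrow_radius)[:, :, None] & (np.abs(z - zc) <= half_h - t)[None, None, :]
        shell = body & ~interior
        labels[body] = v
        cortical |= shell
        fractions[shell] = CORTICAL_FRACTIONS.as_array()
        fractions[interior] = marrow_frac.as_array()

    for (lx, ly, lz), radius in spec.lesions:
        d2 = (
            (x[:, None, None] - lx) ** 2
            + (y[None, :, None] - ly) ** 2
            + (z[None, None, :] - lz) ** 2
        )
        inside = (d2 <= radius**2) & (labels > 0)
        labels[inside] = -1
        cortical &= ~inside
        fractions[inside] = LESION_FRACTIONS.as_array()

    # reference-tissue rods for in-body calibration (label 0, tracked by mask)
    rod_dy = spec.body_radius_mm + 8.0
    rod_r2 = spec.reference_rod_radius_mm**2
    fat_rod = ((x[:, None] - cx) ** 2 + (y[None, :] - (cy - rod_dy)) ** 2 <= rod_r2)[
        :, :, None
    ] & np.ones(nz, bool)[None, None, :]
    muscle_rod = ((x[:, None] - cx) ** 2 + (y[None, :] - (cy + rod_dy)) ** 2 <= rod_r2)[
        :, :, None
    ] & np.ones(nz, bool)[None, None, :]
    fractions[fat_rod] = (1.0, 0.0, 0.0)
    fractions[muscle_rod] = (0.0, 1.0, 0.0)

    tissue = (labels != 0) | fat_rod | muscle_rod
    volumes = {}
    for energy in ("conventional", "low", "high"):
        hu = np.full(spec.grid_shape, AIR_HU, dtype=float)
        hu[tissue] = fractions[tissue] @ basis.hu(energy)
        if energy == "conventional":
            hu[cortical] -= spec.cortical_bh_deficit_hu
        volumes[energy] = hu

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        for energy in ("conventional", "low", "high"):
            volumes[energy] += rng.normal(0.0, spec.noise_sd_hu, spec.grid_shape)

    vol = SpectralVolume(
        conventional=volumes["conventional"],
        low=volumes["low"],
        high=volumes["high"],
        spacing_mm=spec.spacing_mm,
    )
    truth = PhantomTruth(
        label_map=labels,
        fraction_map=fractions,
        true_infiltration=spec.infiltration,
        true_bmd=spec.mineral_fraction(basis) * basis.reference_mineral_density,
        spacing_mm=spec.spacing_mm,
        cortical_mask=cortical,
        fat_ref_mask=fat_rod,
        muscle_ref_mask=muscle_rod,
    )
    return vol, truth


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure: group sizes and per-patient parameter distributions."""

    n_mm: int = 21
    n_mgus: int = 14
    mm_infiltration_dist: tuple[float, float] = (0.72, 0.95)  # Beta shape pair
    mgus_infiltration_dist: tuple[float, float] | None = None  # None: point mass at 0
    bmd_dist: tuple[float, float] = (96.8, 15.0)  # mean, sd in mg/ml
    lesion_prob_mm: float = 13.0 / 21.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mm < 0 or self.n_mgus < 0:
            raise ValueError("group sizes must be non-negative")
        if not 0.0 <= self.lesion_prob_mm <= 1.0:
            raise ValueError("lesion probability must lie in [0, 1]")


def _sample_lesions(
    rng: np.random.Generator, template: PhantomSpec
) -> tuple[tuple[tuple[float, float, float], float], ...]:
    """1-3 osteolytic spheres centred inside random vertebral bodies.

    Radii are drawn from 4-12 mm but capped so the sphere stays within the
    marrow cavity and does not breach the cortical shell.
    """
    nx, ny, _ = template.grid_shape
    sx, sy, _ = template.spacing_mm
    cx, cy = nx * sx / 2.0, ny * sy / 2.0
    pitch = template.body_height_mm + template.gap_mm
    r_max = min(
        12.0,
        template.body_radius_mm - template.cortical_thickness_mm - 1.0,
        template.body_height_mm / 2.0 - template.cortical_thickness_mm - 1.0,
    )
    lesions = []
    for _ in range(int(rng.integers(1, 4))):
        v = int(rng.integers(1, template.n_vertebrae + 1))
        zc = template.gap_mm + (v - 0.5) * pitch
        radius = float(rng.uniform(4.0, max(4.0, r_max)))
        jitter = rng.uniform(-2.0, 2.0, size=2) if r_max + 2.0 < template.body_radius_mm else (0.0, 0.0)
        lesions.append(((cx + jitter[0], cy + jitter[1], zc), radius))
    return tuple(lesions)


def sample_cohort(
    cs: CohortSpec, template: PhantomSpec = DEFAULT_PHANTOM_SPEC
) -> list[tuple[PhantomSpec, dict]]:
    """Draw a cohort of phantoms plus their clinical records.

    Myeloma infiltration follows the configured Beta distribution; MGUS
    defaults to a point mass at zero.  Osteolytic lesions occur only in the
    myeloma group.  Each record also carries three simulated radiologist
    lesion calls (accuracy 0.9 against ground truth).  Reproducible: the
    cohort seed drives everything, per-patient seeds are derived from it.
    """
    ss = np.random.SeedSequence(cs.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    patient_seeds = [int(s) for s in ss.generate_state(cs.n_mm + cs.n_mgus, np.uint32) >> 1]

    cohort: list[tuple[PhantomSpec, dict]] = []
    groups = ["MM"] * cs.n_mm + ["MGUS"] * cs.n_mgus
    for idx, group in enumerate(groups):
        if group == "MM":
            a, b = cs.mm_infiltration_dist
            infiltration = float(rng.beta(a, b))
            has_lesion = bool(rng.random() < cs.lesion_prob_mm)
        else:
            if cs.mgus_infiltration_dist is None:
                infiltration = 0.0
            else:
                a, b = cs.mgus_infiltration_dist
                infiltration = float(rng.beta(a, b))
            has_lesion = False
        bmd = float(np.clip(rng.normal(*cs.bmd_dist), 40.0, 200.0))
        lesions = _sample_lesions(rng, template) if has_lesion else ()
        reader_calls = [
            int(has_lesion) if rng.random() < READER_ACCURACY else 1 - int(has_lesion)
            for _ in range(3)
        ]
        spec = dataclasses.replace(
            template,
            infiltration=infiltration,
            true_bmd_mg_ml=bmd,
            marrow_mineral_fraction=None,
            lesions=lesions,
            seed=patient_seeds[idx],
        )
        n_in_group = idx + 1 if group == "MM" else idx + 1 - cs.n_mm
        record = {
            "patient_id": f"{group}{n_in_group:02d}",
            "group": group,
            "infiltration": infiltration,
            "lesion_truth": int(has_lesion),
            "reader_call_1": reader_calls[0],
            "reader_call_2": reader_calls[1],
            "reader_call_3": reader_calls[2],
            "true_bmd": bmd,
            "seed": patient_seeds[idx],
        }
        cohort.append((spec, record))
    return cohort
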