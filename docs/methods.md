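# Methods

## The measurement model

A marrow voxel is modelled as a volume mixture of three compartments — fat,
soft tissue and bone mineral — whose CT attenuation adds linearly at every
reconstruction energy. With volume fractions `(f_fat, f_soft, f_min)` summing
to one and pure-material Hounsfield values `H_mat(E)`,

    HU(E) = f_fat·H_fat(E) + f_soft·H_soft(E) + f_min·H_min(E).

Mineral attenuation scales linearly with hydroxyapatite-equivalent density;
`H_min` is quoted at a reference density of 400 mg/ml. The default basis
(conventional / low / high energy) is a synthetic convention, not a vendor
calibration:

| material | conventional | low | high |
|---|---|---|---|
| fat | −100 | −110 | −90 |
| soft tissue | +45 | +50 | +40 |
| mineral (400 mg/ml) | +1000 | +1400 | +800 |

### Calcium suppression (VNCa)

Because calcium attenuates disproportionately at low energy, the (low, high)
pair of a voxel determines its mineral fraction. Centred at fat, the pair is
decomposed into a soft-tissue component along `S − F` and a mineral component
along `M − F` (a 2×2 linear solve; the basis is rejected as singular if the
two directions are parallel). Suppression is defined as *replacement*: the
mineral subvolume is replaced by proportionally more of the remaining
fat/soft blend, so at full suppression

    VNCa = (HU_conv − f_min·H_min_conv) / (1 − f_min),

the attenuation of the fat/soft sub-mixture renormalised to the whole voxel.
A vendor-style suppression index scales the removal linearly, `s = index/25`
clipped to [0, 1], so index 25 (the setting used clinically for marrow
reading) means complete suppression. This mapping is a declared convention;
the vendor's is unpublished.

Noise-free mixtures round-trip exactly (mineral removed to ≤ 1e-6 HU), and
zero-mineral voxels are returned unchanged. Voxels whose estimated mineral
fraction is within 1e-6 of 1 have no residual blend; they fall back to plain
subtraction of the mineral term.

### The far-negative cortical peak

Clinical VNCa histograms show a peak far below −1000 HU from densely
calcified structures. An exactly self-consistent linear model cannot produce
it — the renormalised blend is always a convex-range fat/soft value. The
phantom therefore gives cortical-shell voxels a small *beam-hardening
deficit*: their conventional image reads 30 HU (default) below the linear
mixture prediction, emulating the well-known under-reading of dense bone by
single-energy reconstruction relative to a two-material model. The
`1/(1 − f_min)` renormalisation amplifies the deficit — a shell at mineral
fraction 0.98 lands near −1500 HU — reproducing the sub-−1000 peak
qualitatively. Under measurement noise the suppressed values of dense-shell
voxels are numerically unstable (the denominator approaches zero); this
mirrors the clinical fact that VNCa values inside compact bone are
meaningless, and is immaterial here because the cortical shell is eroded out
of the marrow VOI before any statistic is computed.

## Synthetic phantoms and cohorts

Vertebral bodies are cylinders with flat endplates (the quantity under study
is marrow-interior attenuation, not anatomy): default 18 bodies of radius
16 mm and height 24 mm with 4 mm gaps, a 2 mm cortical shell of composition
(fat 0.01, soft 0.01, mineral 0.98), on a 48×48×344 grid at 1.5 mm isotropic
spacing. Two reference-tissue rods (pure fat, pure soft tissue) run along
the spine for in-body calibration. Marrow composition follows an affine
infiltration map,

    f_soft = 0.05 + 0.6·i,   f_min = BMD/400,   f_fat = 1 − f_soft − f_min,

i.e. soft tissue displaces fat at a fixed mineral fraction. The 0.05 base and
0.6 gain are package conventions chosen so that the map stays on the simplex
for any infiltration and any plausible BMD; they are validated only through
monotonicity and recovery properties, not tuned to clinical effect sizes.
Osteolytic lesions are spheres (radius drawn from 4–12 mm, capped so the
sphere stays inside the marrow cavity) whose composition becomes
soft-dominant and mineral-free; their voxels carry label −1 in the truth
map. Acquisition noise is additive Gaussian per energy, independent across
energies, default sd 15 HU.

Cohorts mirror the clinical study structure: 21 myeloma (one smoldering case
folded in) and 14 MGUS patients. Myeloma infiltration is Beta(0.72, 0.95)
(quartiles ≈ 15 / 40 / 69 %, matching the reported 40 % median and
12.5–70 % interquartile range); MGUS infiltration is a point mass at zero.
True BMD is Normal(96.8, 15) mg/ml clipped to [40, 200]. Osteolytic lesions
occur in myeloma only, with probability 13/21. Three simulated radiologists
each call the lesion state correctly with probability 0.9; the consensus is
their majority vote. All randomness descends from one seed through
`numpy.random.SeedSequence`, so phantom and cohort regeneration is
bit-identical.

What the generator does *not* emulate: beam hardening beyond the single
cortical deficit, scatter, correlated inter-energy noise, posterior
elements, anatomically varying vertebra sizes, marrow heterogeneity (the
patchy infiltration morphology of myeloma), and contrast agents. Passing
tests therefore demonstrate the correctness of the computational chain and
its statistical calibration, not scanner-level realism; absolute non-fatty
percentages in phantoms (≈ 12 % at zero infiltration with default noise) sit
well above the sub-1 % clinical range because the two-basis solve amplifies
independent 15 HU noise into roughly 85 HU of VNCa noise.

## Segmentation and quantification

Vertebrae are found by thresholding the conventional image at +200 HU,
filling each closed shell's interior, discarding components below 1 cm³
(noise speckle), and splitting merged bodies at deep minima (prominence
≥ 50 % of the peak) of the axial cross-section profile. Labels are ordered
caudal→cranial along the inferior–superior axis (taken from NIfTI
orientation; fallback last array axis), and the VOI is the union of the 17
most caudal bodies — fewer than 17 is an error, never silently corrected.
An externally produced integer label map can be substituted for the
rule-based labeller; lesion voxels (−1) are then excluded from the VOI.

Cortical bone is removed by morphological erosion with a discrete ball of
physical radius 3 mm honouring anisotropic voxel spacing (semi-axes
`r/spacing` in voxel units); erosion runs on the union mask (equivalent to
per-vertebra erosion for separated bodies). Histograms use left-closed,
right-open 5 HU bins over [−1024, +3071) HU with an out-of-range tally, and
are standardised to a 336.0 cm³ VOI for plotting. The non-fatty portion is
computed from the raw voxel sample, not from binned counts, to avoid 5 HU
quantisation bias; both thresholds are strict (`> 0`, `> −1000`), so a voxel
at exactly 0 HU is fatty and one at exactly −1000 HU is not marrow.

## Phantom-less BMD

Mean conventional HU over fat and muscle reference ROIs define a two-point
affine HU→density calibration applied to the mean HU of the eroded
trabecular interiors of the L1–L3 vertebrae (caudal-ordering positions 3–5
when 17 bodies are counted from L5 upward). A target vertebra intersecting
the lesion mask is dropped and replaced, where possible, by the next more
caudal unused vertebra ("extended to the lower spine"), flagged as
`fallback_used`. The default reference equivalent densities are derived from
the material basis and the uninfiltrated marrow composition
(fat −100 HU ↦ −2.64 mg/ml, muscle +45 HU ↦ 50.09 mg/ml), making the
measurement exact on noise-free phantoms and invariant to global HU drift;
both are configurable when emulating other software conventions. A known
limitation shared with real internal-calibration QCT: marrow-composition
change biases the measurement (here ≈ +32 mg/ml at full infiltration), so
measured BMD and the non-fatty portion are positively correlated in
infiltrated cohorts. Reader repetition for agreement studies jitters ROI
placement by seeded subsampling of the reference and trabecular ROIs.

## Statistics

The infiltration fraction is logit-transformed with the Smithson–Verkuilen
boundary compression `(y(n−1)+0.5)/n` applied uniformly, then regressed on
the non-fatty portion with BMD as a control covariate. Reported inference
uses White-style heteroskedasticity-consistent covariance with a Student-t
reference (n − k df). The default variant is HC1 (the degrees-of-freedom-
corrected White estimator): in 2,000-replicate null simulations at n = 35
the main-predictor test rejects at 6.2 %, inside the nominal band, whereas
uncorrected HC0 rejects at 7.7 % — the classic small-sample liberality that
motivated the MacKinnon–White corrections. HC0/HC2/HC3 remain selectable,
and the textbook HC0 sandwich is exposed as `white_hc0`. Diagnostics:
Breusch–Pagan as `n·R²` of the squared residuals on the design (χ² with k
df), variance inflation factors, and partial, semipartial and whole-model
correlations of the main predictor (all three are reported because "r"
alone is ambiguous).

ROC analysis uses the empirical (Mann–Whitney) AUC with a DeLong 95 %
interval. The Youden operating point maximises sensitivity + specificity − 1
over thresholds placed midway between adjacent observed scores (plus
sentinels outside the range); a patient is positive when the score strictly
exceeds the threshold, and ties in J resolve toward the higher threshold,
i.e. toward specificity. Post-hoc ROC power uses Obuchowski's binormal
variance function for continuous ratings, with the null variance at AUC 0.5
and the alternative variance at the observed AUC; both rejection tails are
counted, so power equals α exactly on the null boundary. Regression sample
size iterates n upward until the noncentral-F power of the 1-df
main-predictor test (noncentrality f²·n, denominator df n − p − 1) reaches
the target. Inter-reader agreement is ICC(2,1) from the two-way
random-effects ANOVA decomposition.

## Numerical and engineering choices

- Left-closed right-open binning; bin membership by `floor((x − lo)/w)`.
- Erosion structuring element: lattice offsets with
  `Σ (d_i·s_i / r)² ≤ 1 + 1e-9`; radius 0 is the identity; a mask that
  erodes to nothing returns empty with a warning.
- The decomposition matrix is rejected as singular when its determinant is
  below 1e-9 relative to the squared basis scale.
- Per-patient failures in a batch are isolated into a failure list with the
  reason; a batch with zero successes is an error. Reports are JSON with
  sorted keys and no timestamps, so identical config + seed reproduce
  byte-identical files; the config digest (SHA-256 of the canonical JSON
  dump) is embedded for provenance.
- Problem sizes: unit tests run on 5-vertebra 32×32×168 phantoms; the
  cohort-level checks use the full 35-patient default geometry (≈ 30 s on
  one CPU). Simulation-based calibration checks use 2,000 replicates for
  test size and 600–800 for power-style rates.

## Known limitations

- The suppression-index map and material basis are conventions; absolute
  VNCa values are not comparable to any specific scanner.
- The non-fatty portion's absolute scale in phantoms depends strongly on the
  noise convention (see above); only ordering and association properties
  transfer to clinical data.
- BMD carries the marrow-composition bias discussed above; the regression's
  BMD covariate is therefore partially collinear with the main predictor in
  heavily infiltrated synthetic cohorts (VIF ≈ 2), unlike the clinical
  report.
- The rule-based labeller assumes closed cortical shells and air-separated
  bodies; real spines require the external-label-map path.
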