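# vnca-marrow

Automated estimation of bone-marrow (BM) infiltration in plasma-cell
disorders — multiple myeloma (MM) and monoclonal gammopathy of undetermined
significance (MGUS) — from dual-energy CT (DECT) after virtual non-calcium
(VNCa) post-processing.

Diagnosing and staging plasma-cell disorders requires an invasive bone-marrow
biopsy to measure the plasma-cell infiltration fraction. DECT offers a
non-invasive proxy: marrow attenuation decomposes into fat, soft tissue and
bone mineral, and removing the calcium-specific contribution (VNCa imaging)
exposes the fat/soft-tissue balance of the marrow. Because cellular
infiltrate displaces fatty marrow, the share of marrow voxels with positive
VNCa attenuation — the **non-fatty portion of BM**,

```
non-fatty portion (%) = 100 · |{ HU_VNCa > 0 }| / |{ HU_VNCa > −1000 }|
```

computed over an automatically segmented 17-vertebra marrow volume of
interest (VOI), rises with biopsy-determined infiltration. Voxels at or
below −1000 HU are calcium-removal artefacts of densely calcified structures
and are excluded from the marrow denominator.

The package implements the full analysis chain as a library plus a thin CLI:

| stage | module | what it does |
|---|---|---|
| phantom simulation | `vnca_marrow.phantom` | dual-energy spine phantoms and MM/MGUS cohorts with known composition, infiltration, BMD and lesion ground truth |
| spectral model | `vnca_marrow.spectral` | linear three-compartment forward model; two-basis inverse and calcium suppression (suppression index 25 = complete removal) |
| segmentation | `vnca_marrow.segmentation` | vertebra labelling (rule-based or imported label map), bottom-up selection of 17 vertebrae, 3 mm cortical erosion on the anisotropic lattice |
| quantification | `vnca_marrow.quantify` | attenuation histograms (5 HU bins, −1024…+3071 HU), VOI standardisation to 336.0 cm³, the non-fatty portion statistic |
| BMD | `vnca_marrow.bmd` | phantom-less (in-body calibrated) trabecular bone mineral density on L1–L3 with caudal fallback past lesioned vertebrae |
| inference | `vnca_marrow.inference` | logit-transformed bounded-response regression with White-robust errors, Breusch–Pagan, VIF, ROC with Youden cutoff and DeLong CI, Obuchowski ROC power, noncentral-F sample size, ICC(2,1), reader majority vote |
| orchestration | `vnca_marrow.pipeline`, `vnca_marrow.cli` | reproducible batch runs: config → JSON report |

Clinical DECT images for this problem are not publicly deposited, so the
synthetic phantom module is a first-class citizen: every downstream stage is
validated against phantoms whose composition, infiltration, density and
lesions are known exactly.

## Worked example

A full synthetic batch mirroring the study cohort (21 MM / 14 MGUS):

```python
from vnca_marrow import load_config, run_pipeline

cfg = load_config(None, seed=7)
report = run_pipeline(cfg, output_dir="run7")   # ~30 s on one CPU
reg = report["inference"]["regression"]
roc = report["inference"]["roc"]["lesions"]
```

With seed 7 this prints (`run7/report.json` holds the full report):

```
n = 35 patients, 0 failures
regression slope (non-fatty % -> logit infiltration): 0.1634, robust p = 1.1e-18
partial r = 0.918, VIF = {non_fatty_percent: 2.07, bmd_mg_ml: 2.07}
ROC (osteolytic lesions):  AUC 0.87 [0.76–0.99], Youden threshold 13.3 %,
                           sens 0.93 / spec 0.70, post-hoc power 0.99
ROC (diagnosis of MM):     AUC 0.97 [0.92–1.00]
inter-reader BMD ICC(2,1) = 0.9998
required n for f² = 0.32 at power 0.8: 27
median non-fatty portion: MM 26.4 %, MGUS 12.3 %
```

Reading the output: the non-fatty portion strongly predicts the generated
infiltration after adjusting for bone mineral density, the threshold rule
separates lesion-positive patients well, and two simulated readers agree
almost perfectly on BMD. Absolute percentages are larger than in clinical
VNCa data because the synthetic noise and compartment conventions are chosen
for testability, not scanner realism — see `docs/methods.md`.

The same run from a shell:

```sh
vnca-marrow run --seed 7 --out run7            # report.json, cohort.csv, histograms.png
vnca-marrow simulate --seed 7 --out cohort7    # NIfTI volumes + truth table
vnca-marrow quantify --conventional p/conventional.nii.gz \
    --low p/low.nii.gz --high p/high.nii.gz --out stat.json
vnca-marrow infer --cohort cohort.csv --out inference.json
```

Identical configuration and seed give a byte-identical `report.json`.

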