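"""Batch orchestration: phantom cohort -> VNCa -> VOI -> statistic -> inference.

Every stage is a pure transform of its inputs; all randomness descends from
the single top-level seed through per-patient derived seeds, so an identical
configuration yields a byte-identical JSON report.  Per-patient failures are
isolated: the offending patient lands in the failure list with its reason and
the batch continues.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .bmd import (
    CalibrationPair,
    derive_calibration_pair,
    internal_calibration,
    measure_bmd,
    roi_mean,
)
from .config import RunConfig, config_hash
from .inference import (
    DecisionRule,
    PowerSpec,
    binarize_diagnosis,
    confusion_metrics,
    fit_infiltration_model,
    icc2,
    majority_vote,
    regression_sample_size,
    roc_youden,
)
from .phantom import CohortSpec, PhantomSpec, build_phantom, sample_cohort
from .quantify import (
    HistogramSpec,
    attenuation_histogram,
    non_fatty_portion,
    standardize_histogram,
)
from .segmentation import (
    erode_cortex,
    extract_voxels,
    label_vertebrae,
    select_bottom_k,
)
from .spectral import MaterialBasis, vnca_transform

log = logging.getLogger("vnca_marrow")

__all__ = ["run_pipeline", "process_patient", "cohort_inference", "write_report"]


def _phantom_template(cfg: RunConfig) -> PhantomSpec:
    p = cfg.phantom
    return PhantomSpec(
        grid_shape=p.grid_shape,
        spacing_mm=p.spacing_mm,
        n_vertebrae=p.n_vertebrae,
        body_radius_mm=p.body_radius_mm,
        body_height_mm=p.body_height_mm,
        gap_mm=p.gap_mm,
        cortical_thickness_mm=p.cortical_thickness_mm,
        base_soft_fraction=p.base_soft_fraction,
        infiltration_gain=p.infiltration_gain,
        noise_sd_hu=p.noise_sd_hu,
        cortical_bh_deficit_hu=p.cortical_bh_deficit_hu,
    )


def _basis(cfg: RunConfig) -> MaterialBasis:
    return MaterialBasis(**cfg.spectral.basis) if cfg.spectral.basis else MaterialBasis()


def _calibration_pair(cfg: RunConfig, basis: MaterialBasis) -> CalibrationPair:
    derived = derive_calibration_pair(basis, cfg.phantom.base_soft_fraction)
    b = cfg.bmd
    if b.density_fat_equiv is None and b.density_muscle_equiv is None:
        return derived
    return CalibrationPair(
        hu_fat_ref=derived.hu_fat_ref,
        hu_muscle_ref=derived.hu_muscle_ref,
        density_fat_equiv=(
            derived.density_fat_equiv if b.density_fat_equiv is None else b.density_fat_equiv
        ),
        density_muscle_equiv=(
            derived.density_muscle_equiv
            if b.density_muscle_equiv is None
            else b.density_muscle_equiv
        ),
    )


def process_patient(
    spec: PhantomSpec, record: dict, cfg: RunConfig
) -> tuple[dict[str, Any], np.ndarray]:
    """All per-patient stages; returns the quantification row and the
    standardised VNCa histogram counts (for cohort plots)."""
    basis = _basis(cfg)
    volume, truth = build_phantom(spec, basis)
    vnca = vnca_transform(volume, basis, cfg.spectral.suppression_index)

    ls = label_vertebrae(
        volume.conventional, spec.spacing_mm, cfg.segmentation.bone_threshold
    )
    voi = erode_cortex(
        select_bottom_k(ls, cfg.segmentation.vertebrae), cfg.segmentation.erosion_mm
    )
    sample, voi_volume = extract_voxels(vnca, voi)
    stat = non_fatty_portion(sample, voi_volume)
    hspec = HistogramSpec(**cfg.histogram.model_dump())
    hist = standardize_histogram(attenuation_histogram(sample, hspec, voi_volume), hspec)

    pair = _calibration_pair(cfg, basis)
    lesion_mask = truth.label_map == -1
    conv = volume.conventional
    cal = internal_calibration(
        roi_mean(conv, truth.muscle_ref_mask), roi_mean(conv, truth.fat_ref_mask), pair
    )
    bmd = measure_bmd(
        conv,
        ls,
        cal,
        target_positions=cfg.bmd.target_positions,
        lesion_mask=lesion_mask,
        erosion_mm=cfg.bmd.roi_erosion_mm,
    )
    reader_bmds = []
    for reader in (1, 2):
        rng = np.random.default_rng([spec.seed, 1000 + reader])
        r_cal = internal_calibration(
            roi_mean(conv, truth.muscle_ref_mask, rng, 0.3),
            roi_mean(conv, truth.fat_ref_mask, rng, 0.3),
            pair,
        )
        reader_bmds.append(
            measure_bmd(
                conv,
                ls,
                r_cal,
                target_positions=cfg.bmd.target_positions,
                lesion_mask=lesion_mask,
                erosion_mm=cfg.bmd.roi_erosion_mm,
                rng=rng,
                subsample=cfg.bmd.reader_subsample,
            ).bmd_mg_ml
        )

    reader_calls = [record[f"reader_call_{i}"] for i in (1, 2, 3)]
    row = {
        "patient_id": record["patient_id"],
        "group": record["group"],
        "infiltration": record["infiltration"],
        "true_bmd": record["true_bmd"],
        "lesion_truth": record["lesion_truth"],
        "reader_call_1": reader_calls[0],
        "reader_call_2": reader_calls[1],
        "reader_call_3": reader_calls[2],
        "lesion_call": majority_vote(reader_calls),
        "voi_volume_cm3": voi_volume,
        "n_marrow": stat.n_marrow,
        "n_above_zero": stat.n_above_zero,
        "non_fatty_percent": stat.non_fatty_percent,
        "bmd_mg_ml": bmd.bmd_mg_ml,
        "bmd_vertebrae_used": "|".join(map(str, bmd.vertebrae_used)),
        "bmd_fallback_used": int(bmd.fallback_used),
        "reader_bmd_1": reader_bmds[0],
        "reader_bmd_2": reader_bmds[1],
        "seed": record["seed"],
    }
    return row, hist.standardized_counts


def _roc_block(res, rule_metrics) -> dict[str, Any]:
    return {
        "auc": res.auc,
        "ci95": list(res.ci95),
        "youden_threshold": res.youden_threshold,
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "power_at_alpha": res.power_at_alpha,
        "cutoff_rule": rule_metrics,
    }


def _rule_metrics(calls: np.ndarray, outcome: np.ndarray) -> dict[str, Any]:
    tp = int(((calls == 1) & (outcome == 1)).sum())
    fn = int(((calls == 0) & (outcome == 1)).sum())
    tn = int(((calls == 0) & (outcome == 0)).sum())
    fp = int(((calls == 1) & (outcome == 0)).sum())
    m = confusion_metrics(tp, fn, tn, fp)
    return {
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
    }


def cohort_inference(table: pd.DataFrame, cfg: RunConfig) -> dict[str, Any]:
    """Regression, ROC (lesions and diagnosis), decision rule, ICC and
    sample-size blocks from the per-patient quantification table."""
    out: dict[str, Any] = {}
    try:
        reg = fit_infiltration_model(table)
    except ValueError as exc:
        out["regression"] = {"error": str(exc)}
        reg = None
    if reg is not None:
        out["regression"] = {
            "params": reg.params,
            "robust_se": reg.robust_se,
            "p_values": reg.p_values,
            "partial_r": reg.partial_r,
            "semipartial_r": reg.semipartial_r,
            "model_r": reg.model_r,
            "vif": reg.vif,
            "breusch_pagan": {"stat": reg.bp_stat, "p": reg.bp_p},
            "n": reg.n,
        }

    scores = table["non_fatty_percent"].to_numpy(float)
    rule = DecisionRule(cfg.inference.cutoff_percent)
    calls = rule(scores)
    diagnosis = np.array(
        [binarize_diagnosis(g, i) for g, i in zip(table["group"], table["infiltration"])]
    )
    outcomes = {}
    if cfg.inference.outcome in ("lesions", "both"):
        outcomes["lesions"] = table["lesion_call"].to_numpy(int)
    if cfg.inference.outcome in ("diagnosis", "both"):
        outcomes["diagnosis"] = diagnosis
    out["roc"] = {}
    for name, y in outcomes.items():
        if len(np.unique(y)) < 2:
            out["roc"][name] = {"error": "single-class outcome"}
            continue
        res = roc_youden(scores, y, alpha=cfg.inference.alpha)
        out["roc"][name] = _roc_block(res, _rule_metrics(calls, y))

    reader_cols = ["reader_bmd_1", "reader_bmd_2"]
    if all(c in table for c in reader_cols) and len(table) >= 3:
        try:
            out["icc2_bmd"] = icc2(table[reader_cols].to_numpy(float))
        except ValueError as exc:
            out["icc2_bmd"] = {"error": str(exc)}

    ps = PowerSpec(
        f2=cfg.inference.f2, alpha=cfg.inference.alpha, power=cfg.inference.target_power
    )
    out["regression_sample_size"] = {
        "f2": ps.f2,
        "alpha": ps.alpha,
        "target_power": ps.power,
        "n_predictors": ps.n_predictors,
        "required_n": regression_sample_size(ps),
    }
    return out


def run_pipeline(cfg: RunConfig, output_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the full synthetic batch and return the run report.

    When ``output_dir`` is set (or configured), writes ``report.json``, the
    per-patient ``cohort.csv`` and a group-mean standardised histogram plot.
    """
    t0 = time.time()
    template = _phantom_template(cfg)
    cohort = sample_cohort(CohortSpec(**cfg.cohort.model_dump(), seed=cfg.seed), template)

    rows: list[dict] = []
    failures: list[dict] = []
    hists: dict[str, list[np.ndarray]] = {}
    for spec, record in cohort:
        t_pat = time.time()
        try:
            row, hist = process_patient(spec, record, cfg)
            rows.append(row)
            hists.setdefault(record["group"], []).append(hist)
        except Exception as exc:  # isolate per-patient failures
            failures.append({"patient_id": record["patient_id"], "reason": str(exc)})
        log.info("patient %s done in %.2fs", record["patient_id"], time.time() - t_pat)

    if not rows:
        raise RuntimeError("zero successful patients")
    table = pd.DataFrame(rows)

    report: dict[str, Any] = {
        "provenance": {
            "software": "vnca-marrow",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": config_hash(cfg),
        },
        "n_patients": len(rows),
        "patients": rows,
        "failures": failures,
        "inference": cohort_inference(table, cfg),
    }
    log.info("batch of %d patients finished in %.1fs", len(rows), time.time() - t0)

    out_dir = Path(output_dir) if output_dir is not None else None
    if out_dir is not None:
        write_report(report, table, hists, out_dir)
    return report


def write_report(
    report: dict[str, Any],
    table: pd.DataFrame,
    hists: dict[str, list[np.ndarray]],
    out_dir: Path,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    table.to_csv(out_dir / "cohort.csv", index=False)
    _plot_histograms(hists, out_dir / "histograms.png")


def _plot_histograms(hists: dict[str, list[np.ndarray]], path: Path) -> None:
    if not hists:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = HistogramSpec()
    centers = spec.edges[:-1] + spec.bin_width / 2.0
    fig, ax = plt.subplots(figsize=(7, 4))
    for group, stack in sorted(hists.items()):
        mean = np.mean(np.stack(stack), axis=0)
        ax.plot(centers, mean, label=f"{group} (n={len(stack)})", lw=1.2)
    ax.set_xlim(-1250, 400)
    ax.set_xlabel("VNCa attenuation (HU)")
    ax.set_ylabel("standardised voxel count / 5 HU")
    ax.axvline(0.0, color="k", ls=":", lw=0.8)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
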