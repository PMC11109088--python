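"""End-to-end pipeline driver on a simulated cohort.

Runs simulate -> ADC / T1 / DCE fitting -> VOI response statistics ->
pixel-wise prediction, writes the tables as CSV/JSON (optionally the maps
as NIfTI), and — because the cohort is synthetic — scores the recovery of
the programmed responder labels against the ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import (LABEL_ARTERY, LABEL_TUMOR_START, PARAMETERS, ParameterMap,
                   ValidationError)
from . import adc as adc_mod
from . import dce as dce_mod
from . import io as io_mod
from . import phantom as ph
from . import pixelwise as px
from . import response as rs
from . import t1map as t1_mod

log = logging.getLogger("qmripd")

__all__ = ["StudyConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class StudyConfig:
    """Configuration of a simulated-cohort pipeline run."""

    cohort: ph.CohortConfig = field(default_factory=ph.CohortConfig)
    effects: str = "default"  # 'default' | 'null'
    responder_fraction: float = 0.5
    seed: int = 0
    adc_group_fallback: float = 0.8e-3
    literature_rc: Optional[dict] = None
    aif_top_k: int = 10
    iauc_window_s: float = 90.0
    tree_max_depth: int = 2
    tree_repeats: int = 10
    lopo_repeats: int = 5
    run_pixelwise: bool = True
    write_nifti: bool = False
    output_dir: Optional[str] = None

    def effect_model(self) -> ph.TreatmentEffectModel:
        if self.effects == "default":
            return ph.TreatmentEffectModel.default_day1(self.responder_fraction)
        if self.effects == "null":
            return ph.TreatmentEffectModel.null()
        raise ValidationError(f"unknown effects preset {self.effects!r}")


def load_config(path: "str | Path") -> StudyConfig:
    """Build a StudyConfig from a YAML file; validation errors are raised
    before any computation."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort = ph.CohortConfig(**raw.pop("cohort", {}))
    known = {f for f in StudyConfig.__dataclass_fields__ if f != "cohort"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(cohort=cohort, **raw)


@dataclass
class PipelineResult:
    cohort: ph.PhantomCohort
    cohort_table: pd.DataFrame  # labeled CohortTable
    adc_rc: rs.RCResult
    rc_spec: rs.RCSpec
    thresholds: pd.DataFrame
    association: dict
    recovery: dict  # truth-vs-pipeline responder metrics
    aif_per_patient: dict
    pixel_dataset: Optional[pd.DataFrame] = None
    tree_model: Optional[px.TreeModel] = None
    lopo: Optional[dict] = None


def _fit_visit_maps(scene, cfg: ph.CohortConfig, noise, rng) -> dict:
    """Simulate one visit's acquisitions and fit all six parameter maps.
    Returns maps plus the per-replicate ADC fits and the extracted AIF."""
    out: dict = {}
    # --- diffusion ---
    dwi_reps = ph.simulate_dwi(scene, cfg.b_values_s_mm2, cfg.dwi_replicates,
                               noise, rng)
    rep_fits = [adc_mod.fit_adc(s, expected_b=cfg.b_values_s_mm2) for s in dwi_reps]
    out["adc_replicates"] = rep_fits
    out["adc"] = adc_mod.combine_replicates(rep_fits)
    # --- T1 ---
    vfa = ph.simulate_vfa(scene, cfg.flip_angles_deg, cfg.tr_ms, noise, rng)
    t1fit = t1_mod.fit_t1_vfa(vfa)
    out["t1"] = t1fit.t1_map()
    # --- dynamic ---
    dyn = ph.simulate_dce(scene, ph.CohortConfig.make_aif(cfg), cfg.frame_interval_s,
                          cfg.dce_frames, cfg.n_baseline_frames,
                          cfg.dce_flip_angle_deg, cfg.tr_ms,
                          cfg.relaxivity_per_mM_s, noise, rng)
    artery = scene.labels == LABEL_ARTERY
    inj, baseline_frames = dce_mod.detect_injection(dyn, artery_mask=artery,
                                                    override=cfg.n_baseline_frames)
    # blood T1 from the VFA fit is unreliable (long T1 -> tiny high-angle
    # signal), so the artery uses the configured reference blood T1 for the
    # concentration conversion, as is standard when a measured value is poor
    t1_conv = ParameterMap(values=out["t1"].values.copy(), units="s",
                           valid=out["t1"].valid.copy(), name="t1")
    t1_conv.values[artery] = cfg.blood_t1_s
    t1_conv.valid |= artery
    conc = dce_mod.signal_to_concentration(dyn, t1_conv, cfg.relaxivity_per_mM_s,
                                           baseline_frames=baseline_frames)
    aif = dce_mod.extract_aif(conc, artery)
    out["aif"] = aif
    out["iauc"] = dce_mod.compute_iauc(conc)
    # extended Tofts on tumor voxels only
    shape = scene.shape
    for name in ("ktrans", "ve", "vp"):
        out[name] = ParameterMap(values=np.full(shape, np.nan), units="", name=name,
                                 valid=np.zeros(shape, dtype=bool))
    out["ktrans"].units, out["iauc"].units = "min^-1", "mM*s"
    tumor_any = scene.labels >= LABEL_TUMOR_START
    if np.any(tumor_any):
        curves = conc.conc_mM[tumor_any]
        pk = dce_mod.fit_extended_tofts(curves, aif, times_s=conc.times_s)
        for name, vals in (("ktrans", pk.ktrans_per_min), ("ve", pk.ve),
                           ("vp", pk.vp)):
            out[name].values[tumor_any] = vals
            out[name].valid[tumor_any] = pk.valid
    return out


def run_pipeline(config: StudyConfig) -> PipelineResult:
    """Execute the full simulate -> fit -> respond -> pixel-wise chain."""
    rng = np.random.default_rng(config.seed)
    cfg = config.cohort
    noise = cfg.noise_model()
    effect = config.effect_model()
    log.info("generating cohort: %d patients, visits %s", cfg.n_patients, cfg.visits)
    cohort = ph.generate_ground_truth(cfg, effect, rng)

    fitted: dict = {}
    rows = []
    rep_rows = []
    aif_per_patient = {}
    for pid, visits in cohort.scenes.items():
        fitted[pid] = {}
        for visit, scene in visits.items():
            maps = _fit_visit_maps(scene, cfg, noise, rng)
            fitted[pid][visit] = maps
            aif_per_patient.setdefault(pid, {})[visit] = maps["aif"]
            for lab in scene.tumor_labels():
                tid = f"T{lab - LABEL_TUMOR_START + 1}"
                mask = scene.tumor_mask(lab)
                ctx = f"{pid}/{tid}/{visit}"
                for p in PARAMETERS:
                    rows.append({"patient_id": pid, "tumor_id": tid,
                                 "visit": visit, "parameter": p,
                                 "median": rs.voi_medians(maps[p].as_map()
                                                          if hasattr(maps[p], "as_map")
                                                          else maps[p], mask, ctx)})
                if visit == "baseline":
                    for f in maps["adc_replicates"]:
                        rep_rows.append({
                            "patient_id": pid, "tumor_id": tid,
                            "replicate": f.replicate,
                            "median": rs.voi_medians(f.as_map(), mask, ctx)})

    table = pd.DataFrame(rows)
    adc_rc = rs.rc_from_replicates(pd.DataFrame(rep_rows))
    rc_spec = rs.build_rc_spec(adc_rc=adc_rc,
                               adc_group_fallback=config.adc_group_fallback,
                               literature=config.literature_rc)
    labeled = rs.label_responders(table, rc_spec)

    # baseline-threshold models per parameter, better of the two directions
    thr_rows = []
    day1 = labeled[(labeled["visit"] == "day1") & labeled["label"].notna()]
    for p, grp in day1.groupby("parameter"):
        y = grp["label"].to_numpy()
        if np.unique(y).size < 2:
            log.warning("%s: single response class, threshold model skipped", p)
            continue
        models = [rs.optimize_threshold(grp["baseline"].to_numpy(), y, d)
                  for d in (">", "<")]
        m = max(models, key=lambda m: m.balanced_accuracy)
        thr_rows.append({"parameter": p, "direction": m.direction,
                         "cutpoint": m.cutpoint, "sensitivity": m.sensitivity,
                         "specificity": m.specificity,
                         "balanced_accuracy": m.balanced_accuracy,
                         "mcnemar_p": m.mcnemar_p})
    thresholds = pd.DataFrame(thr_rows)
    try:
        association = rs.association_stats(labeled)
    except ValidationError as e:
        log.warning("association statistics skipped: %s", e)
        association = {"regression": pd.DataFrame(),
                       "change_correlations": pd.DataFrame()}

    # --- recovery of the programmed truth ---
    truth = cohort.truth.copy()
    tr_labels, pred_labels = [], []
    lab_idx = day1.set_index(["patient_id", "tumor_id", "parameter"])["label"]
    for r in truth.itertuples():
        pred = lab_idx.get((r.patient_id, r.tumor_id, r.parameter))
        if pred is None:
            continue
        if r.parameter == "iauc":
            band = rc_spec.band("iauc")
            lo, hi = band.limits(r.baseline_true)
            t = (r.day1_true - r.baseline_true) > hi
        else:
            t = bool(r.responder_true)
        tr_labels.append(t)
        pred_labels.append(pred == "P")
    recovery = rs.classification_metrics(np.array(pred_labels), np.array(tr_labels))
    recovery["n"] = len(tr_labels)

    # --- pixel-wise stage ---
    pixel_dataset = tree_model = lopo = None
    if config.run_pixelwise and len(cfg.visits) > 1:
        records = []
        per_patient_maps, per_patient_masks = {}, {}
        for pid, visits in fitted.items():
            scene = cohort.scenes[pid]["baseline"]
            tumor_any = scene.labels >= LABEL_TUMOR_START
            per_patient_maps[pid] = [f.adc for f in visits["baseline"]["adc_replicates"]]
            per_patient_masks[pid] = tumor_any
        group_rc = px.group_pixel_rc(per_patient_maps, per_patient_masks,
                                     rng=np.random.default_rng(config.seed + 1))
        for pid, visits in fitted.items():
            scene = cohort.scenes[pid]["baseline"]
            base_maps, day1_maps = visits["baseline"], visits["day1"]
            for lab in scene.tumor_labels():
                tid = f"T{lab - LABEL_TUMOR_START + 1}"
                mask = scene.tumor_mask(lab)
                try:
                    t_rc = px.pixel_rc([f.adc for f in base_maps["adc_replicates"]],
                                       mask)
                except ValidationError:
                    t_rc = group_rc
                base = {p: base_maps[p].values[mask] for p in PARAMETERS}
                day1v = {p: day1_maps[p].values[mask] for p in PARAMETERS}
                lab_masks = px.label_pixels(base, day1v, rc_spec, adc_pixel_rc=t_rc)
                ok = np.ones(next(iter(base.values())).shape, dtype=bool)
                for p in PARAMETERS:
                    ok &= np.isfinite(base[p]) & np.isfinite(day1v[p])
                records.append({"patient_id": pid, "tumor_id": tid,
                                "baseline": {p: base[p][ok] for p in PARAMETERS},
                                "p_responder": lab_masks["any"][ok]})
        pixel_dataset = px.build_pixel_dataset(records)
        if pixel_dataset["p_responder"].nunique() == 2:
            tree_model = px.train_threshold_tree(
                pixel_dataset, max_depth=config.tree_max_depth,
                n_repeats=config.tree_repeats, seed=config.seed + 2)
            lopo = px.lopo_evaluate(pixel_dataset, max_depth=config.tree_max_depth,
                                    n_repeats=config.lopo_repeats,
                                    seed=config.seed + 3)
        else:
            log.warning("pixel dataset has a single class; tree stage skipped")

    result = PipelineResult(cohort=cohort, cohort_table=labeled, adc_rc=adc_rc,
                            rc_spec=rc_spec, thresholds=thresholds,
                            association=association, recovery=recovery,
                            aif_per_patient=aif_per_patient,
                            pixel_dataset=pixel_dataset, tree_model=tree_model,
                            lopo=lopo)
    if config.output_dir:
        _write_outputs(result, fitted, config)
    return result


def _write_outputs(result: PipelineResult, fitted: dict, config: StudyConfig) -> None:
    out = Path(config.output_dir)
    io_mod.write_csv(result.cohort_table, out / "cohort_table.csv")
    io_mod.write_csv(result.adc_rc.per_tumor, out / "adc_rc_per_tumor.csv")
    io_mod.write_csv(result.thresholds, out / "thresholds.csv")
    io_mod.write_csv(result.association["regression"], out / "association_regression.csv")
    io_mod.write_csv(result.association["change_correlations"],
                     out / "change_correlations.csv")
    io_mod.write_csv(result.cohort.truth, out / "ground_truth.csv")
    for pid, visits in result.aif_per_patient.items():
        for visit, aif in visits.items():
            io_mod.write_csv(pd.DataFrame({"time_s": aif.times_s,
                                           "Cp_mM": aif.cp_mM}),
                             out / "aif" / f"{pid}_{visit}.csv")
    ba = result.adc_rc.bland_altman
    summary = {
        "seed": config.seed,
        "adc_group_rc": result.adc_rc.group_rc,
        "bland_altman": {"bias": ba.bias, "loa_lower": ba.loa_lower,
                         "loa_upper": ba.loa_upper, "n_pairs": ba.n_pairs},
        "recovery": result.recovery,
        "thresholds": result.thresholds.to_dict(orient="records"),
    }
    if result.tree_model is not None:
        summary["tree_model"] = {
            "rules": [list(r) for r in result.tree_model.rules],
            "training_ba": result.tree_model.training_ba,
            "mean_validation_ba": result.tree_model.mean_validation_ba,
        }
        io_mod.write_json(summary["tree_model"], out / "tree_model.json")
    if result.lopo is not None:
        summary["lopo"] = result.lopo
        io_mod.write_csv(pd.DataFrame(
            {"patient_id": list(result.lopo["per_patient_ba"]),
             "ba": list(result.lopo["per_patient_ba"].values())}),
            out / "lopo.csv")
    if result.pixel_dataset is not None:
        io_mod.write_csv(result.pixel_dataset, out / "pixel_dataset.csv")
    io_mod.write_json(summary, out / "summary.json")
    if config.write_nifti:
        for pid, visits in fitted.items():
            for visit, maps in visits.items():
                for p in PARAMETERS:
                    pm = maps[p].as_map() if hasattr(maps[p], "as_map") else maps[p]
                    io_mod.save_map(pm, out / "maps" / f"{pid}_{visit}_{p}",
                                    spacing_mm=config.cohort.spacing_mm)
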