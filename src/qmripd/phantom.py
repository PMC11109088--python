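"""Digital phantom cohorts with known ground truth.

Generates multi-patient, multi-visit scenes carrying true ADC, T1, M0,
k^trans, v_e and v_p maps plus a label map (background / normal tissue /
artery / tumors), applies programmed day-1 treatment effects to the truth
maps, and simulates the three acquisition types (diffusion-weighted,
variable-flip-angle, dynamic contrast-enhanced) with Rician or Gaussian
noise. Because effects are applied to parameter maps rather than to signals,
every downstream responder label has an unambiguous ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DECREASE_PARAMS,
    LABEL_ARTERY,
    LABEL_BACKGROUND,
    LABEL_NORMAL,
    LABEL_TUMOR_START,
    AIF,
    ImageSeries,
    NoiseModel,
    ValidationError,
    as_rng,
    spgr_signal,
)
from . import dce

__all__ = [
    "GroundTruthScene",
    "EffectRule",
    "TreatmentEffectModel",
    "CohortConfig",
    "PhantomCohort",
    "generate_ground_truth",
    "simulate_dwi",
    "simulate_vfa",
    "simulate_dce",
    "add_noise",
    "generate_pixel_cohort",
]

GT_PARAMS = ("adc", "t1", "m0", "ktrans", "ve", "vp")


@dataclass
class GroundTruthScene:
    """One visit's true parameter maps on a voxel grid."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    maps: dict  # name -> (nx, ny, nz) array for each of GT_PARAMS
    labels: np.ndarray  # integer label map
    visit: str
    patient_id: str = ""

    def __post_init__(self) -> None:
        missing = [p for p in GT_PARAMS if p not in self.maps]
        if missing:
            raise ValidationError(f"ground-truth maps missing {missing}")
        fg = self.labels != LABEL_BACKGROUND
        ve, vp = self.maps["ve"], self.maps["vp"]
        if np.any(ve < 0) or np.any(vp < 0) or np.any(ve + vp > 1.0 + 1e-9):
            raise ValidationError("need 0 <= v_e, v_p and v_e + v_p <= 1 everywhere")
        if np.any(self.maps["adc"] < 0):
            raise ValidationError("ADC must be >= 0")
        if np.any(self.maps["t1"][fg] <= 0):
            raise ValidationError("T1 must be > 0 on foreground voxels")
        art = self.labels == LABEL_ARTERY
        if np.any(art) and (np.any(vp[art] != 1.0) or np.any(ve[art] != 0.0)):
            raise ValidationError("artery voxels must have v_p = 1, v_e = 0")

    def tumor_labels(self) -> list[int]:
        labs = np.unique(self.labels)
        return [int(l) for l in labs if l >= LABEL_TUMOR_START]

    def tumor_mask(self, tumor_label: int) -> np.ndarray:
        return self.labels == tumor_label


@dataclass
class EffectRule:
    """Programmed day-1 change of one parameter.

    ``mode`` 'additive' adds ``amount`` (parameter units), 'multiplicative'
    multiplies by ``amount``. ``gate`` selects which tumors respond:
    ('all',), ('none',), ('above', c) / ('below', c) on the tumor's baseline
    value, or ('fraction', f) for a random draw. ``recovery`` is the fraction
    of the effect remaining per visit after day 1 (parameters drift back
    toward baseline).
    """

    mode: str  # 'additive' | 'multiplicative'
    amount: float
    gate: tuple = ("all",)
    recovery: float = 0.35

    def applies(self, baseline_value: float, rng: np.random.Generator) -> bool:
        kind = self.gate[0]
        if kind == "all":
            return True
        if kind == "none":
            return False
        if kind == "above":
            return baseline_value > self.gate[1]
        if kind == "below":
            return baseline_value < self.gate[1]
        if kind == "fraction":
            return bool(rng.random() < self.gate[1])
        raise ValidationError(f"unknown gate {self.gate!r}")

    def delta(self, baseline: np.ndarray, visit_index: int) -> np.ndarray:
        """Signed change applied at visit_index (1 = day 1)."""
        if self.mode == "additive":
            full = np.full_like(baseline, self.amount, dtype=float)
        elif self.mode == "multiplicative":
            full = baseline * (self.amount - 1.0)
        else:
            raise ValidationError(f"unknown effect mode {self.mode!r}")
        return full * (self.recovery ** (visit_index - 1))


@dataclass
class TreatmentEffectModel:
    """Per-parameter day-1 effect rules with a recovery schedule."""

    rules: dict = field(default_factory=dict)  # parameter -> EffectRule

    @classmethod
    def null(cls) -> "TreatmentEffectModel":
        return cls(rules={})

    @classmethod
    def default_day1(cls, responder_fraction: float = 0.5) -> "TreatmentEffectModel":
        """Effects mirroring the observed pharmacodynamics: ADC and T1
        decrease, k^trans/v_e/v_p increase on day 1, each by twice the
        repeatability band used downstream (T1 0.27 s absolute; k^trans
        +83% relative; v_e 0.076 and v_p 0.0062 absolute). The ADC decrease
        of 0.15e-3 mm^2/s is ~10% of a typical tumor baseline, well above
        replicate repeatability at the default noise level."""
        g = ("fraction", responder_fraction)
        return cls(rules={
            "adc": EffectRule("additive", -0.15e-3, gate=g),
            "t1": EffectRule("additive", -2 * 0.27, gate=g),
            "ktrans": EffectRule("multiplicative", 1.0 + 2 * 0.83, gate=g),
            "ve": EffectRule("additive", +2 * 0.076, gate=g),
            "vp": EffectRule("additive", +2 * 0.0062, gate=g),
        })


@dataclass
class CohortConfig:
    """Geometry, tissue-parameter ranges and acquisition settings for a
    simulated cohort. Defaults give a desk-scale cohort matching the study
    protocol: DWI at b = {0, 450} s/mm^2 with 3 replicates, VFA at
    {15, 23, 30, 60} degrees with TR 3 ms, and a >40-frame dynamic series
    every 8 s at 30 degrees."""

    n_patients: int = 6
    tumors_per_patient: int = 1
    shape: tuple[int, int, int] = (32, 32, 8)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 8.0)
    visits: tuple[str, ...] = ("baseline", "day1")
    tumor_radius_vox: tuple[float, float] = (3.5, 5.5)
    # baseline tumor parameter ranges (uniform per tumor)
    adc_range: tuple[float, float] = (1.0e-3, 2.0e-3)  # mm^2/s
    t1_range: tuple[float, float] = (0.7, 1.3)  # s
    ktrans_range: tuple[float, float] = (0.03, 0.2)  # min^-1
    ve_range: tuple[float, float] = (0.1, 0.4)
    vp_range: tuple[float, float] = (0.01, 0.05)
    m0: float = 1000.0
    intra_tumor_cv: float = 0.03  # voxelwise spread around the tumor value
    # normal tissue / blood reference values
    normal_values: dict = field(default_factory=lambda: {
        "adc": 1.2e-3, "t1": 0.58, "ktrans": 0.02, "ve": 0.25, "vp": 0.02})
    blood_t1_s: float = 1.4
    blood_adc: float = 3.0e-3
    # acquisition
    b_values_s_mm2: tuple[float, ...] = (0.0, 450.0)
    dwi_replicates: int = 3
    flip_angles_deg: tuple[float, ...] = (15.0, 23.0, 30.0, 60.0)
    tr_ms: float = 3.0
    dce_frames: int = 48
    frame_interval_s: float = 8.0
    n_baseline_frames: int = 6
    dce_flip_angle_deg: float = 30.0
    relaxivity_per_mM_s: float = 4.5
    snr: float = 50.0
    noise_family: str = "rician"

    def __post_init__(self) -> None:
        # YAML configs arrive with lists; normalize the tuple-typed fields
        for f in ("shape", "spacing_mm", "visits", "tumor_radius_vox",
                  "adc_range", "t1_range", "ktrans_range", "ve_range",
                  "vp_range", "b_values_s_mm2", "flip_angles_deg"):
            setattr(self, f, tuple(getattr(self, f)))
        if self.n_patients < 1 or self.tumors_per_patient < 1:
            raise ValidationError("need >= 1 patient and >= 1 tumor per patient")
        if len(self.visits) < 1 or self.visits[0] != "baseline":
            raise ValidationError("visits must start with 'baseline'")
        if self.ve_range[1] + self.vp_range[1] > 1.0:
            raise ValidationError("v_e + v_p ranges may exceed 1: inconsistent config")
        for lo, hi in (self.adc_range, self.t1_range, self.ktrans_range,
                       self.ve_range, self.vp_range):
            if not 0 <= lo <= hi:
                raise ValidationError("parameter ranges must satisfy 0 <= lo <= hi")
        if not 1 <= self.n_baseline_frames < self.dce_frames:
            raise ValidationError("n_baseline_frames must be in [1, n_frames)")

    def noise_model(self) -> NoiseModel:
        return NoiseModel(family=self.noise_family, snr=self.snr)

    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.dce_frames) * self.frame_interval_s

    def injection_time_s(self) -> float:
        return self.n_baseline_frames * self.frame_interval_s

    def make_aif(self) -> AIF:
        # extend the grid slightly so interpolation at frame times is covered
        t = np.arange(self.dce_frames + 1) * self.frame_interval_s
        return dce.analytic_aif(t, self.injection_time_s())


@dataclass
class PhantomCohort:
    """Scenes per patient and visit plus the programmed ground truth."""

    config: CohortConfig
    effect_model: TreatmentEffectModel
    scenes: dict  # patient_id -> {visit -> GroundTruthScene}
    truth: pd.DataFrame  # patient_id, tumor_id, parameter, baseline/day1 truth, responder
    aif: AIF

    @property
    def patient_ids(self) -> list[str]:
        return list(self.scenes)


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def generate_ground_truth(
    config: CohortConfig,
    effect_model: TreatmentEffectModel,
    seed: "int | np.random.Generator | None" = None,
) -> PhantomCohort:
    """Generate per-visit ground-truth scenes for a cohort.

    Deterministic under a fixed seed. The truth table records, per tumor and
    parameter, the baseline and day-1 true VOI medians and the programmed
    responder flag (whether the effect rule was applied, in the parameter's
    pharmacodynamic response direction). iAUC truth is derived from the
    noiseless forward model of the tumor-median kinetic parameters.
    """
    rng = as_rng(seed)
    aif = config.make_aif()
    nx, ny, nz = config.shape
    scenes: dict = {}
    rows = []
    ranges = {"adc": config.adc_range, "t1": config.t1_range,
              "ktrans": config.ktrans_range, "ve": config.ve_range,
              "vp": config.vp_range}

    for p in range(config.n_patients):
        pid = f"P{p + 1:03d}"
        labels = np.full(config.shape, LABEL_NORMAL, dtype=int)
        # artery: small cylinder along z near the volume edge
        art = _ellipsoid_mask(config.shape, (2.5, ny / 2, nz / 2),
                              (2.0, 2.0, nz))
        labels[art] = LABEL_ARTERY

        tumor_values: dict[int, dict[str, float]] = {}
        placed = 0
        attempts = 0
        while placed < config.tumors_per_patient and attempts < 200:
            attempts += 1
            r_xy = rng.uniform(*config.tumor_radius_vox)
            r_z = max(1.2, r_xy * nz / nx)
            cx = rng.uniform(8 + r_xy, nx - r_xy - 2)
            cy = rng.uniform(r_xy + 2, ny - r_xy - 2)
            cz = rng.uniform(r_z, nz - r_z)
            m = _ellipsoid_mask(config.shape, (cx, cy, cz), (r_xy, r_xy, r_z))
            if np.any(labels[m] != LABEL_NORMAL):
                continue
            lab = LABEL_TUMOR_START + placed
            labels[m] = lab
            tumor_values[lab] = {k: rng.uniform(*ranges[k]) for k in ranges}
            placed += 1
        if placed < config.tumors_per_patient:
            raise ValidationError("could not place tumors without overlap; "
                                  "reduce radius or count")

        # baseline maps
        base_maps = {}
        for k in ("adc", "t1", "ktrans", "ve", "vp"):
            m = np.zeros(config.shape)
            m[labels == LABEL_NORMAL] = config.normal_values[k]
            if k == "t1":
                m[labels == LABEL_ARTERY] = config.blood_t1_s
            elif k == "adc":
                m[labels == LABEL_ARTERY] = config.blood_adc
            elif k == "vp":
                m[labels == LABEL_ARTERY] = 1.0
            else:
                m[labels == LABEL_ARTERY] = 0.0
            for lab, vals in tumor_values.items():
                tm = labels == lab
                jitter = 1.0 + config.intra_tumor_cv * rng.standard_normal(int(tm.sum()))
                m[tm] = vals[k] * np.clip(jitter, 0.5, 1.5)
            base_maps[k] = m
        m0 = np.zeros(config.shape)
        m0[labels != LABEL_BACKGROUND] = config.m0
        base_maps["m0"] = m0
        # keep the ve + vp <= 1 invariant after jitter
        over = base_maps["ve"] + base_maps["vp"] > 1.0
        base_maps["ve"][over] = 1.0 - base_maps["vp"][over]

        # responder assignment per tumor x parameter (fixed for all visits)
        applied: dict[tuple[int, str], bool] = {}
        for lab, vals in tumor_values.items():
            for param, rule in effect_model.rules.items():
                applied[(lab, param)] = rule.applies(vals[param], rng)

        visit_scenes = {}
        tumor_kinetics: dict[int, dict[str, dict[str, float]]] = {lab: {} for lab in tumor_values}
        for vi, visit in enumerate(config.visits):
            maps = {k: v.copy() for k, v in base_maps.items()}
            if vi > 0:
                for param, rule in effect_model.rules.items():
                    for lab in tumor_values:
                        if not applied[(lab, param)]:
                            continue
                        tm = labels == lab
                        maps[param][tm] = maps[param][tm] + rule.delta(maps[param][tm], vi)
                # restore invariants after effects
                maps["adc"] = np.clip(maps["adc"], 0.0, None)
                maps["t1"][labels != LABEL_BACKGROUND] = np.clip(
                    maps["t1"][labels != LABEL_BACKGROUND], 0.05, 10.0)
                maps["ktrans"] = np.clip(maps["ktrans"], 0.0, None)
                maps["vp"] = np.clip(maps["vp"], 0.0, 1.0)
                maps["ve"] = np.clip(maps["ve"], 0.0, 1.0 - maps["vp"])
            scene = GroundTruthScene(shape=config.shape, spacing_mm=config.spacing_mm,
                                     maps=maps, labels=labels, visit=visit,
                                     patient_id=pid)
            visit_scenes[visit] = scene
            for lab in tumor_values:
                tm = labels == lab
                tumor_kinetics[lab][visit] = {
                    k: float(np.median(maps[k][tm]))
                    for k in ("adc", "t1", "ktrans", "ve", "vp")}
        scenes[pid] = visit_scenes

        # truth table rows (day-1 response vs baseline)
        times = config.frame_times_s()
        for lab in tumor_values:
            tid = f"T{lab - LABEL_TUMOR_START + 1}"
            med = tumor_kinetics[lab]
            iauc_by_visit = {}
            for visit in config.visits:
                ct = dce.tofts_forward(med[visit]["ktrans"], med[visit]["ve"],
                                       med[visit]["vp"], aif, times)
                conc = dce.ConcentrationSeries(
                    conc_mM=ct[None, :], times_s=times,
                    injection_frame=config.n_baseline_frames,
                    r1_per_mM_s=config.relaxivity_per_mM_s,
                    valid=np.array([True]), clipped_negative=np.array([False]))
                iauc_by_visit[visit] = float(dce.compute_iauc(conc).values[0])
            day1 = config.visits[1] if len(config.visits) > 1 else None
            for param in ("adc", "t1", "ktrans", "ve", "vp", "iauc"):
                if param == "iauc":
                    base_v = iauc_by_visit["baseline"]
                    day1_v = iauc_by_visit[day1] if day1 else np.nan
                    resp = None  # decided by the band on the truth change downstream
                else:
                    base_v = med["baseline"][param]
                    day1_v = med[day1][param] if day1 else np.nan
                    rule = effect_model.rules.get(param)
                    if rule is None:
                        resp = False
                    else:
                        direction = -1.0 if param in DECREASE_PARAMS else 1.0
                        d = rule.delta(np.array([base_v]), 1)[0]
                        resp = bool(applied[(lab, param)] and d * direction > 0)
                rows.append({"patient_id": pid, "tumor_id": tid, "parameter": param,
                             "baseline_true": base_v, "day1_true": day1_v,
                             "responder_true": resp})

    truth = pd.DataFrame(rows)
    return PhantomCohort(config=config, effect_model=effect_model,
                         scenes=scenes, truth=truth, aif=aif)


# ---------------------------------------------------------------------------
# signal simulators
# ---------------------------------------------------------------------------

def add_noise(series: ImageSeries, noise: NoiseModel,
              rng: "int | np.random.Generator | None" = None,
              reference_signal: Optional[float] = None) -> ImageSeries:
    """Apply Rician or Gaussian noise to a series; seeded and reproducible.

    Rician: out = sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2).
    """
    if noise.family == "none":
        return series
    if rng is None:
        rng = noise.seed
    rng = as_rng(rng)
    ref = reference_signal if reference_signal is not None else float(
        np.max(np.abs(series.data))) or 1.0
    sigma = noise.sigma_for(ref)
    if sigma == 0.0:
        return series
    data = series.data
    if noise.family == "gaussian":
        out = data + sigma * rng.standard_normal(data.shape)
    else:
        n1 = sigma * rng.standard_normal(data.shape)
        n2 = sigma * rng.standard_normal(data.shape)
        out = np.sqrt((data + n1) ** 2 + n2 ** 2)
    return replace(series, data=out)


def simulate_dwi(scene: GroundTruthScene, b_values_s_mm2: Sequence[float],
                 n_replicates: int = 3, noise: Optional[NoiseModel] = None,
                 rng: "int | np.random.Generator | None" = None) -> list[ImageSeries]:
    """Mono-exponential diffusion series S(b) = S0 exp(-b ADC), one stack per
    replicate; replicates differ only by their noise realization."""
    b = np.asarray(b_values_s_mm2, dtype=float)
    if b.size == 0:
        raise ValidationError("b_values must be nonempty")
    if np.any(b < 0) or n_replicates < 1:
        raise ValidationError("need b >= 0 and n_replicates >= 1")
    rng = as_rng(rng)
    s0 = scene.maps["m0"]
    clean = s0[..., None] * np.exp(-b[None, None, None, :] * scene.maps["adc"][..., None])
    out = []
    for r in range(n_replicates):
        series = ImageSeries(data=clean.copy(), kind="dwi",
                             spacing_mm=scene.spacing_mm, b_values_s_mm2=b,
                             replicate=r,
                             series_id=f"{scene.patient_id}/{scene.visit}/dwi{r}")
        if noise is not None:
            fg = scene.labels != LABEL_BACKGROUND
            series = add_noise(series, noise, rng,
                               reference_signal=float(np.mean(clean[fg])) or 1.0)
        out.append(series)
    return out


def simulate_vfa(scene: GroundTruthScene, flip_angles_deg: Sequence[float],
                 tr_ms: float, noise: Optional[NoiseModel] = None,
                 rng: "int | np.random.Generator | None" = None) -> ImageSeries:
    """Variable-flip-angle SPGR series from the true T1 and M0 maps."""
    fas = np.asarray(flip_angles_deg, dtype=float)
    if fas.size < 1:
        raise ValidationError("need >= 1 flip angle")
    if tr_ms <= 0:
        raise ValidationError("TR must be positive")
    vols = [spgr_signal(scene.maps["t1"], scene.maps["m0"], fa, tr_ms) for fa in fas]
    data = np.stack(vols, axis=-1)
    fg = scene.labels != LABEL_BACKGROUND
    data[~fg] = 0.0
    series = ImageSeries(data=data, kind="vfa", spacing_mm=scene.spacing_mm,
                         flip_angles_deg=fas, tr_ms=tr_ms,
                         series_id=f"{scene.patient_id}/{scene.visit}/vfa")
    if noise is not None:
        # SNR is defined against the series' own mean foreground signal
        series = add_noise(series, noise, as_rng(rng),
                           reference_signal=float(np.mean(data[fg])) or 1.0)
    return series


def simulate_dce(scene: GroundTruthScene, aif: AIF, frame_interval_s: float,
                 n_frames: int, n_baseline_frames: int, flip_angle_deg: float,
                 tr_ms: float, relaxivity_per_mM_s: float,
                 noise: Optional[NoiseModel] = None,
                 rng: "int | np.random.Generator | None" = None) -> ImageSeries:
    """Dynamic SPGR series: tissue concentration from the extended Tofts
    forward model, T1(t) via 1/T1(t) = 1/T1(0) + r1 C(t), then the SPGR
    signal at the dynamic flip angle. Artery voxels (v_p = 1) carry the AIF
    itself."""
    if not 1 <= n_baseline_frames < n_frames:
        raise ValidationError("n_baseline_frames must be in [1, n_frames)")
    times = np.arange(n_frames) * frame_interval_s
    fg = scene.labels != LABEL_BACKGROUND
    kt = scene.maps["ktrans"][fg]
    ve = scene.maps["ve"][fg]
    vp = scene.maps["vp"][fg]
    ct = dce.tofts_forward(kt, ve, vp, aif, times)  # (V, T)
    ct[:, :n_baseline_frames] = 0.0
    t1_0 = scene.maps["t1"][fg][:, None]
    r1_t = 1.0 / t1_0 + relaxivity_per_mM_s * ct
    m0 = scene.maps["m0"][fg][:, None]
    sig = spgr_signal(1.0 / r1_t, m0, flip_angle_deg, tr_ms)
    data = np.zeros(scene.shape + (n_frames,))
    data[fg] = sig
    series = ImageSeries(data=data, kind="dce", spacing_mm=scene.spacing_mm,
                         flip_angle_deg=flip_angle_deg, tr_ms=tr_ms,
                         frame_times_s=times, injection_frame=n_baseline_frames,
                         series_id=f"{scene.patient_id}/{scene.visit}/dce")
    if noise is not None:
        # SNR against the mean pre-injection foreground signal
        ref = float(np.mean(sig[:, :n_baseline_frames])) or 1.0
        series = add_noise(series, noise, as_rng(rng), reference_signal=ref)
    return series


# ---------------------------------------------------------------------------
# pixel-level cohort (statistics-scale phantom)
# ---------------------------------------------------------------------------

def generate_pixel_cohort(
    n_patients: int = 6,
    pixels_per_tumor: tuple[int, int] = (100, 400),
    rule_feature: str = "ve",
    rule_cutpoint: float = 0.39,
    rule_direction: str = "<",
    label_noise: float = 0.05,
    seed: "int | np.random.Generator | None" = None,
    feature_ranges: Optional[dict] = None,
) -> pd.DataFrame:
    """Tumor-voxel table with a planted baseline rule driving p-response.

    Each patient contributes one tumor of random size; the six baseline
    parameters are drawn per pixel and the p-responder label follows
    ``rule_feature rule_direction rule_cutpoint`` with ``label_noise``
    probability of a flipped label. Used to exercise the pixel-wise
    predictor at the statistics scale without image simulation.
    """
    rng = as_rng(seed)
    if feature_ranges is None:
        feature_ranges = {"adc": (0.8e-3, 2.2e-3), "t1": (0.3, 1.5),
                          "iauc": (2.0, 20.0), "ktrans": (0.01, 0.3),
                          "ve": (0.1, 0.7), "vp": (0.005, 0.08)}
    rows = []
    for p in range(n_patients):
        n_pix = int(rng.integers(pixels_per_tumor[0], pixels_per_tumor[1] + 1))
        feats = {k: rng.uniform(lo, hi, n_pix) for k, (lo, hi) in feature_ranges.items()}
        x = feats[rule_feature]
        label = x < rule_cutpoint if rule_direction == "<" else x > rule_cutpoint
        flip = rng.random(n_pix) < label_noise
        label = label ^ flip
        df = pd.DataFrame(feats)
        df.insert(0, "patient_id", f"P{p + 1:03d}")
        df.insert(1, "tumor_id", "T1")
        df["p_responder"] = label
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
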