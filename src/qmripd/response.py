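"""VOI-level response statistics.

Implements the QIBA-style repeatability framework: per-tumor repeatability
coefficients RC = 2.77 sqrt(sigma^2) from replicate VOI medians (2.77 =
1.96 sqrt(2), so 95% of replicate differences fall inside +/-RC), responder
labeling of day-1 changes against per-parameter RC bands, balanced-accuracy
threshold discovery on baseline values, and the supporting association and
inter-observer agreement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _mcnemar

from .core import DECREASE_PARAMS, PARAMETERS, ParameterMap, ValidationError

__all__ = [
    "RCBand", "RCSpec", "ThresholdModel", "BlandAltman", "RCResult",
    "voi_medians", "rc_from_replicates", "build_rc_spec", "label_responders",
    "classification_metrics", "optimize_threshold", "association_stats",
    "icc_interobserver", "DEFAULT_LITERATURE_RC",
]

RC_FACTOR = 2.77  # QIBA: RC = 2.77 sqrt(within-subject variance)

#: literature repeatability bands for the parameters without replicate scans
DEFAULT_LITERATURE_RC = {
    "t1": {"band": "absolute", "rc": 0.27},            # s
    "iauc": {"band": "relative", "pct": 32.0},         # % of baseline
    "ktrans": {"band": "asymmetric-relative", "lower_pct": -45.0, "upper_pct": 83.0},
    "ve": {"band": "absolute", "rc": 0.076},
    "vp": {"band": "absolute", "rc": 0.0062},
}


@dataclass
class RCBand:
    """Significance band of one parameter.

    ``band`` 'absolute' uses +/-``rc`` in parameter units; 'relative' uses
    +/-``pct``% of |baseline|; 'asymmetric-relative' uses ``lower_pct``% /
    ``upper_pct``% of baseline. ``direction`` is the pharmacodynamic
    response direction ('decrease' or 'increase').
    """

    band: str
    direction: str
    rc: Optional[float] = None
    pct: Optional[float] = None
    lower_pct: Optional[float] = None
    upper_pct: Optional[float] = None
    provenance: str = "literature"
    per_tumor_rc: dict = field(default_factory=dict)  # (patient_id, tumor_id) -> RC

    def __post_init__(self) -> None:
        if self.band == "absolute":
            if self.rc is None or self.rc < 0:
                raise ValidationError("absolute band needs rc >= 0")
        elif self.band == "relative":
            if self.pct is None or self.pct < 0:
                raise ValidationError("relative band needs pct >= 0")
        elif self.band == "asymmetric-relative":
            if self.lower_pct is None or self.upper_pct is None:
                raise ValidationError("asymmetric band needs lower_pct and upper_pct")
            if not (self.lower_pct <= 0 <= self.upper_pct):
                raise ValidationError("need lower_pct <= 0 <= upper_pct")
        else:
            raise ValidationError(f"unknown band type {self.band!r}")
        if self.direction not in ("decrease", "increase"):
            raise ValidationError("direction must be 'decrease' or 'increase'")

    def limits(self, baseline: float,
               tumor_key: Optional[tuple] = None) -> tuple[float, float]:
        """(lower, upper) change limits; changes outside are significant."""
        if self.band == "absolute":
            rc = self.per_tumor_rc.get(tumor_key, self.rc) if tumor_key else self.rc
            return -rc, rc
        if self.band == "relative":
            half = abs(baseline) * self.pct / 100.0
            return -half, half
        return (baseline * self.lower_pct / 100.0, baseline * self.upper_pct / 100.0)


@dataclass
class RCSpec:
    """Per-parameter repeatability bands with response directions."""

    bands: dict  # parameter -> RCBand

    def __post_init__(self) -> None:
        for p, b in self.bands.items():
            expected = "decrease" if p in DECREASE_PARAMS else "increase"
            if b.direction != expected:
                raise ValidationError(
                    f"{p}: response direction must be {expected!r}")

    def band(self, parameter: str) -> RCBand:
        if parameter not in self.bands:
            raise ValidationError(f"parameter {parameter!r} missing from the RC spec")
        return self.bands[parameter]


@dataclass
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float
    n_pairs: int


@dataclass
class RCResult:
    per_tumor: pd.DataFrame  # patient_id, tumor_id, sigma2, rc, n_replicates
    group_rc: float
    bland_altman: BlandAltman


@dataclass
class ThresholdModel:
    parameter: str
    direction: str  # '>' : baseline > cut predicts response; '<' the converse
    cutpoint: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    mcnemar_p: float

    def __post_init__(self) -> None:
        ba = (self.sensitivity + self.specificity) / 2.0
        if np.isfinite(ba) and abs(ba - self.balanced_accuracy) > 1e-12:
            raise ValidationError("BA must equal (sensitivity + specificity)/2")

    def predict(self, baseline: np.ndarray) -> np.ndarray:
        baseline = np.asarray(baseline, dtype=float)
        return baseline > self.cutpoint if self.direction == ">" else baseline < self.cutpoint


# ---------------------------------------------------------------------------

def voi_medians(pmap: ParameterMap, mask: np.ndarray, context: str = "") -> float:
    """Median of valid, finite in-mask voxels (even count: mean of the
    central pair)."""
    mask = np.asarray(mask, dtype=bool)
    vals = pmap.values[mask & pmap.valid]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError(
            f"VOI median undefined: no valid voxel in mask {context or '(unnamed)'}")
    return float(np.median(vals))


def rc_from_replicates(medians: pd.DataFrame) -> RCResult:
    """Per-tumor and group repeatability from replicate VOI medians.

    ``medians`` needs columns patient_id, tumor_id, median (one row per
    replicate). sigma^2 is the within-tumor variance of replicate medians
    (ddof=1), RC = 2.77 sqrt(sigma^2); the group RC is the median of
    per-tumor RCs. The Bland-Altman summary pools all within-tumor replicate
    pair differences: bias = mean difference, limits = bias +/- 1.96 SD.
    """
    required = {"patient_id", "tumor_id", "median"}
    if not required <= set(medians.columns):
        raise ValidationError(f"replicate table needs columns {sorted(required)}")
    rows, diffs = [], []
    for (pid, tid), grp in medians.groupby(["patient_id", "tumor_id"]):
        vals = grp["median"].to_numpy(dtype=float)
        if vals.size >= 2:
            s2 = float(np.var(vals, ddof=1))
            rows.append({"patient_id": pid, "tumor_id": tid, "sigma2": s2,
                         "rc": RC_FACTOR * np.sqrt(s2), "n_replicates": vals.size})
            diffs.extend(b - a for a, b in combinations(vals, 2))
    if not rows:
        raise ValidationError("no tumor has >= 2 replicates: RC not derivable")
    per_tumor = pd.DataFrame(rows)
    diffs = np.asarray(diffs, dtype=float)
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    bias = float(diffs.mean())
    ba = BlandAltman(bias=bias, loa_lower=bias - 1.96 * sd,
                     loa_upper=bias + 1.96 * sd, n_pairs=diffs.size)
    return RCResult(per_tumor=per_tumor,
                    group_rc=float(per_tumor["rc"].median()),
                    bland_altman=ba)


def build_rc_spec(
    adc_rc: Optional[RCResult] = None,
    adc_group_fallback: float = 0.8e-3,
    literature: Optional[dict] = None,
    parameters: Sequence[str] = PARAMETERS,
) -> RCSpec:
    """Assemble the per-parameter RC bands.

    ADC uses the replicate-derived per-tumor RC where available, otherwise
    the group RC (``adc_rc.group_rc`` when replicates exist, else
    ``adc_group_fallback``). The other parameters use configured literature
    bands (see :data:`DEFAULT_LITERATURE_RC`).
    """
    lit = dict(DEFAULT_LITERATURE_RC)
    if literature:
        lit.update(literature)
    bands = {}
    for p in parameters:
        direction = "decrease" if p in DECREASE_PARAMS else "increase"
        if p == "adc":
            group = adc_rc.group_rc if adc_rc is not None else adc_group_fallback
            per_tumor = {}
            if adc_rc is not None:
                per_tumor = {(r.patient_id, r.tumor_id): r.rc
                             for r in adc_rc.per_tumor.itertuples()}
            bands[p] = RCBand(band="absolute", direction=direction, rc=group,
                              per_tumor_rc=per_tumor, provenance="replicates")
        else:
            if p not in lit:
                raise ValidationError(f"no RC source for parameter {p!r}")
            bands[p] = RCBand(direction=direction, provenance="literature", **lit[p])
    return RCSpec(bands=bands)


def label_responders(table: pd.DataFrame, spec: RCSpec,
                     day1_visit: str = "day1") -> pd.DataFrame:
    """Annotate a tidy cohort table with changes, significance and P/N labels.

    ``table`` has one row per (patient_id, tumor_id, visit, parameter) with a
    ``median`` column and a 'baseline' visit. Adds ``baseline``, ``delta``,
    ``flag`` ('below', 'within', 'above') for every post-baseline visit, and
    ``label`` ('P'/'N') on the day-1 visit: P iff the significant change is
    in the parameter's response direction.
    """
    required = {"patient_id", "tumor_id", "visit", "parameter", "median"}
    if not required <= set(table.columns):
        raise ValidationError(f"cohort table needs columns {sorted(required)}")
    out = table.copy()
    base = (out[out["visit"] == "baseline"]
            .set_index(["patient_id", "tumor_id", "parameter"])["median"])
    out["baseline"] = [
        base.get((r.patient_id, r.tumor_id, r.parameter), np.nan)
        for r in out.itertuples()]
    out["delta"] = out["median"] - out["baseline"]
    flags, labels = [], []
    for r in out.itertuples():
        if r.visit == "baseline" or not np.isfinite(r.baseline) or not np.isfinite(r.delta):
            flags.append(None)
            labels.append(None)
            continue
        band = spec.band(r.parameter)
        lo, hi = band.limits(r.baseline, tumor_key=(r.patient_id, r.tumor_id))
        flag = "below" if r.delta < lo else ("above" if r.delta > hi else "within")
        flags.append(flag)
        if r.visit != day1_visit:
            labels.append(None)
        else:
            responded = (flag == "below") if band.direction == "decrease" else (flag == "above")
            labels.append("P" if responded else "N")
    out["flag"] = flags
    out["label"] = labels
    return out


# ---------------------------------------------------------------------------

def _to_bool_labels(v) -> np.ndarray:
    """Coerce P/N ('PP'/'PN'), boolean or 0/1 label vectors to booleans."""
    v = np.asarray(v)
    if v.dtype == bool:
        return v
    if np.issubdtype(v.dtype, np.number):
        return v > 0
    return np.isin(v, ("P", "PP"))


def _mcnemar_p(pred: np.ndarray, true: np.ndarray) -> float:
    """McNemar test on the paired (predicted, true) discordant counts:
    exact binomial below 25 discordant pairs, continuity-corrected chi^2
    otherwise."""
    n01 = int(np.sum(~pred & true))
    n10 = int(np.sum(pred & ~true))
    n00 = int(np.sum(~pred & ~true))
    n11 = int(np.sum(pred & true))
    if n01 + n10 == 0:
        return 1.0
    exact = (n01 + n10) < 25
    res = _mcnemar([[n11, n10], [n01, n00]], exact=exact, correction=True)
    return float(res.pvalue)


def classification_metrics(pred, true) -> dict:
    """Sensitivity = |PP ∩ P| / |P|, specificity = |PN ∩ N| / |N|,
    BA = (sensitivity + specificity)/2, and the McNemar p-value.

    Inputs are boolean arrays or 'P'/'N' ('PP'/'PN') label vectors. A zero
    denominator leaves that component NaN; BA then averages the defined
    components and ``single_class`` is flagged.
    """
    pred_b, true_b = _to_bool_labels(pred), _to_bool_labels(true)
    if pred_b.shape != true_b.shape:
        raise ValidationError("label vectors differ in length")
    if pred_b.size == 0:
        raise ValidationError("empty label vectors")
    n_pos = int(true_b.sum())
    n_neg = int((~true_b).sum())
    sens = float(np.sum(pred_b & true_b) / n_pos) if n_pos else float("nan")
    spec = float(np.sum(~pred_b & ~true_b) / n_neg) if n_neg else float("nan")
    defined = [x for x in (sens, spec) if np.isfinite(x)]
    ba = float(np.mean(defined)) if defined else float("nan")
    return {"sensitivity": sens, "specificity": spec, "balanced_accuracy": ba,
            "mcnemar_p": _mcnemar_p(pred_b, true_b),
            "single_class": len(defined) < 2}


def optimize_threshold(baseline, labels, direction: str) -> ThresholdModel:
    """Exhaustive balanced-accuracy-maximizing cutpoint on baseline values.

    Candidates are the midpoints of consecutive sorted distinct values plus
    -inf/+inf. Ties are broken toward the cutpoint with the larger minimum
    distance to any observed value (class margin), then the smaller
    cutpoint. ``direction`` '>' predicts response for baseline > c, '<' for
    baseline < c.
    """
    if direction not in (">", "<"):
        raise ValidationError("direction must be '>' or '<'")
    x = np.asarray(baseline, dtype=float)
    y = _to_bool_labels(labels)
    if x.size != y.size or x.size == 0:
        raise ValidationError("baseline values and labels must pair up")
    if y.all() or (~y).all():
        raise ValidationError("threshold search needs both classes present")
    xs = np.unique(x)
    cands = np.concatenate([[-np.inf], (xs[:-1] + xs[1:]) / 2.0, [np.inf]])
    best = None
    for c in cands:
        pred = x > c if direction == ">" else x < c
        sens = np.sum(pred & y) / y.sum()
        spec = np.sum(~pred & ~y) / (~y).sum()
        ba = (sens + spec) / 2.0
        margin = np.min(np.abs(x - c)) if np.isfinite(c) else 0.0
        key = (ba, margin, -c if np.isfinite(c) else -np.inf)
        if best is None or key > best[0]:
            best = (key, c, sens, spec, ba, pred)
    _, c, sens, spec, ba, pred = best
    return ThresholdModel(parameter="", direction=direction, cutpoint=float(c),
                          sensitivity=float(sens), specificity=float(spec),
                          balanced_accuracy=float(ba),
                          mcnemar_p=_mcnemar_p(pred, y))


def association_stats(labeled: pd.DataFrame, method: str = "pearson",
                      day1_visit: str = "day1") -> dict:
    """Regressions of day-1 change on baseline, and pairwise correlations
    among parameter changes.

    Returns ``{"regression": DataFrame, "change_correlations": DataFrame}``:
    per parameter an OLS of delta on baseline (slope, R^2, F-test p), and
    for each parameter pair the correlation of their day-1 changes across
    tumors (Pearson by default, Spearman on request) with its p-value.
    """
    import statsmodels.api as sm

    d1 = labeled[(labeled["visit"] == day1_visit)
                 & np.isfinite(labeled["delta"])
                 & np.isfinite(labeled["baseline"])]
    reg_rows = []
    for p, grp in d1.groupby("parameter"):
        if len(grp) < 3:
            raise ValidationError(f"{p}: need >= 3 paired observations")
        x = grp["baseline"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        fit = sm.OLS(grp["delta"].to_numpy(), X).fit()
        reg_rows.append({"parameter": p, "slope": float(fit.params[1]),
                         "intercept": float(fit.params[0]),
                         "r_squared": float(fit.rsquared),
                         "f_pvalue": float(fit.f_pvalue), "n": len(grp)})
    wide = d1.pivot_table(index=["patient_id", "tumor_id"], columns="parameter",
                          values="delta")
    corr_rows = []
    params = list(wide.columns)
    for i, a in enumerate(params):
        for b in params[i + 1:]:
            pair = wide[[a, b]].dropna()
            if len(pair) < 3:
                continue
            if method == "pearson":
                r, p = stats.pearsonr(pair[a], pair[b])
            elif method == "spearman":
                r, p = stats.spearmanr(pair[a], pair[b])
            else:
                raise ValidationError(f"unknown correlation method {method!r}")
            corr_rows.append({"param_a": a, "param_b": b, "r": float(r),
                              "p_value": float(p), "n": len(pair)})
    return {"regression": pd.DataFrame(reg_rows),
            "change_correlations": pd.DataFrame(corr_rows)}


def icc_interobserver(obs1, obs2, visits=None) -> pd.DataFrame:
    """Inter-observer agreement of per-tumor medians.

    Two-way random-effects, absolute-agreement, single-measures ICC (ICC2)
    per visit plus pooled over all points. ``obs1``/``obs2`` are paired
    arrays; ``visits`` optionally groups the pairs.
    """
    import pingouin as pg

    obs1 = np.asarray(obs1, dtype=float)
    obs2 = np.asarray(obs2, dtype=float)
    if obs1.shape != obs2.shape or obs1.size < 2:
        raise ValidationError("need >= 2 paired observations")
    visits = np.asarray(visits) if visits is not None else np.full(obs1.size, "all")

    def icc2(a, b):
        n = a.size
        df = pd.DataFrame({
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["o1", "o2"], n),
            "score": np.concatenate([a, b])})
        res = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="score")
        # two-way random, absolute agreement, single measures
        hit = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
        return float(hit["ICC"].iloc[0])

    rows = []
    for v in pd.unique(visits):
        m = visits == v
        if m.sum() >= 2:
            rows.append({"visit": v, "icc": icc2(obs1[m], obs2[m]),
                         "n": int(m.sum())})
    rows.append({"visit": "overall", "icc": icc2(obs1, obs2), "n": obs1.size})
    return pd.DataFrame(rows)
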