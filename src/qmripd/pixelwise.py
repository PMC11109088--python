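"""Pixel-level responder labeling and the baseline decision-rule model.

Every tumor voxel is labeled a p-responder when any parameter's day-1
change exceeds its repeatability band in the pharmacodynamic direction
(below -RC for ADC and T1, above +RC otherwise). A depth-capped CART
decision tree on the six baseline parameters is then trained with
patient-balanced, class-balanced sampling — per draw, every patient
contributes the same number of pixels, equal to 85% of the smallest tumor's
pixel count — and evaluated per patient on held-out pixels and by
leave-one-patient-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .core import DECREASE_PARAMS, PARAMETERS, ValidationError, as_rng
from .response import RC_FACTOR, RCSpec, classification_metrics

__all__ = ["TreeModel", "pixel_rc", "group_pixel_rc", "label_pixels",
           "build_pixel_dataset", "train_threshold_tree", "lopo_evaluate",
           "DEFAULT_GROUP_PIXEL_RC"]

#: group pixel-wise ADC repeatability fallback, mm^2/s
DEFAULT_GROUP_PIXEL_RC = 1.4e-3

FEATURES = list(PARAMETERS)


@dataclass
class TreeModel:
    """Decision rules extracted from a depth-capped CART tree.

    ``rules`` lists (feature, '<', threshold) tuples from the root down the
    first split path; the root rule is the headline single-feature
    predictor. ``estimator`` keeps the fitted tree for prediction.
    """

    rules: list
    depth: int
    training_ba: float
    validation_ba_per_patient: dict
    mean_validation_ba: float
    estimator: DecisionTreeClassifier = field(repr=False, default=None)

    @property
    def root_feature(self) -> str:
        return self.rules[0][0]

    @property
    def root_cutpoint(self) -> float:
        return self.rules[0][2]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(X[FEATURES].to_numpy()).astype(bool)


# ---------------------------------------------------------------------------
# pixel repeatability
# ---------------------------------------------------------------------------

def pixel_rc(replicate_maps: Sequence[np.ndarray], tumor_mask: np.ndarray) -> float:
    """Per-tumor pixel-wise RC = 2.77 sqrt(pooled within-pixel replicate
    variance) from co-registered replicate ADC maps."""
    if len(replicate_maps) < 2:
        raise ValidationError("need >= 2 replicates for a pixel-wise RC")
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    stack = np.stack([np.asarray(m, dtype=float)[tumor_mask] for m in replicate_maps])
    ok = np.all(np.isfinite(stack), axis=0)
    if not np.any(ok):
        raise ValidationError("no tumor pixel valid in all replicates")
    pooled = float(np.mean(np.var(stack[:, ok], axis=0, ddof=1)))
    return RC_FACTOR * float(np.sqrt(pooled))


def group_pixel_rc(per_patient_maps: dict, per_patient_masks: dict,
                   rng=None) -> float:
    """Group pixel-wise RC pooled over patients with equal pixel counts.

    ``per_patient_maps``: patient -> list of replicate maps;
    ``per_patient_masks``: patient -> tumor mask. Each patient contributes
    the same number of randomly sampled pixels (the smallest patient's
    count) to the pooled variance.
    """
    rng = as_rng(rng)
    per_pixel_vars = {}
    for pid, maps in per_patient_maps.items():
        if len(maps) < 2:
            continue
        mask = np.asarray(per_patient_masks[pid], dtype=bool)
        stack = np.stack([np.asarray(m, dtype=float)[mask] for m in maps])
        ok = np.all(np.isfinite(stack), axis=0)
        if np.any(ok):
            per_pixel_vars[pid] = np.var(stack[:, ok], axis=0, ddof=1)
    if not per_pixel_vars:
        raise ValidationError("no patient has >= 2 valid replicates")
    n = min(v.size for v in per_pixel_vars.values())
    pooled = np.concatenate([rng.choice(v, size=n, replace=False)
                             for v in per_pixel_vars.values()])
    return RC_FACTOR * float(np.sqrt(pooled.mean()))


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def label_pixels(baseline_maps: dict, day1_maps: dict, spec: RCSpec,
                 adc_pixel_rc: Optional[float] = None) -> dict:
    """Per-parameter p-responder masks and the combined any-parameter label.

    ``baseline_maps``/``day1_maps`` map parameter name -> voxel array (all
    six parameters required, co-registered). The ADC band uses
    ``adc_pixel_rc`` (per-tumor or group pixel-wise RC) when given,
    otherwise the spec's ADC band. Returns ``{parameter: bool array, ...,
    'any': bool array}``.
    """
    missing = [p for p in PARAMETERS if p not in baseline_maps or p not in day1_maps]
    if missing:
        raise ValidationError(f"missing parameter maps: {missing}")
    out = {}
    combined = None
    for p in PARAMETERS:
        base = np.asarray(baseline_maps[p], dtype=float)
        delta = np.asarray(day1_maps[p], dtype=float) - base
        band = spec.band(p)
        if p == "adc" and adc_pixel_rc is not None:
            lo, hi = np.full_like(base, -adc_pixel_rc), np.full_like(base, adc_pixel_rc)
        else:
            lims = [band.limits(b) for b in base.ravel()]
            lo = np.array([l for l, _ in lims]).reshape(base.shape)
            hi = np.array([h for _, h in lims]).reshape(base.shape)
        resp = delta < lo if band.direction == "decrease" else delta > hi
        resp = resp & np.isfinite(delta)
        out[p] = resp
        combined = resp if combined is None else (combined | resp)
    out["any"] = combined
    return out


def build_pixel_dataset(records: Sequence[dict]) -> pd.DataFrame:
    """Assemble the flat pixel table from per-tumor voxel records.

    Each record: patient_id, tumor_id, ``baseline`` dict of parameter ->
    1D voxel values, and ``p_responder`` boolean array of the same length.
    """
    frames = []
    for rec in records:
        df = pd.DataFrame({p: np.asarray(rec["baseline"][p], dtype=float)
                           for p in PARAMETERS})
        df.insert(0, "patient_id", rec["patient_id"])
        df.insert(1, "tumor_id", rec["tumor_id"])
        df["p_responder"] = np.asarray(rec["p_responder"], dtype=bool)
        frames.append(df)
    if not frames:
        raise ValidationError("no pixel records")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _per_patient_sample_size(dataset: pd.DataFrame, fraction: float = 0.85) -> int:
    smallest = dataset.groupby(["patient_id", "tumor_id"]).size().min()
    n = int(np.floor(fraction * smallest))
    if n < 2:
        raise ValidationError("smallest tumor too small for the sampling protocol")
    return n


def _balanced_draw(dataset: pd.DataFrame, n_per_patient: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Indices of a training draw: ``n_per_patient`` pixels per patient with
    the two classes globally balanced (|#responder - #non-responder| <= 1).

    Patients with both classes start at an even split; a patient carrying a
    single class contributes only that class, and the other patients' splits
    shift to restore the global balance. Sampling is with replacement when a
    patient's class pool is smaller than its share.
    """
    patients = sorted(dataset["patient_id"].unique())
    pools = {}
    quotas = {}
    extra_to_pos = True
    for pid in patients:
        sub = dataset.index[dataset["patient_id"] == pid]
        lab = dataset.loc[sub, "p_responder"].to_numpy()
        pools[pid] = (sub[lab], sub[~lab])
        pos_pool, neg_pool = pools[pid]
        if len(pos_pool) == 0 and len(neg_pool) == 0:
            raise ValidationError(f"patient {pid} has no pixels")
        n_pos = n_per_patient // 2
        n_neg = n_per_patient - n_pos
        if n_per_patient % 2:
            if not extra_to_pos:
                n_pos, n_neg = n_neg, n_pos
            extra_to_pos = not extra_to_pos
        if len(pos_pool) == 0:
            n_pos, n_neg = 0, n_per_patient
        elif len(neg_pool) == 0:
            n_pos, n_neg = n_per_patient, 0
        quotas[pid] = [n_pos, n_neg]
    # shift one pixel at a time between the classes of flexible patients
    # until the draw is globally balanced
    def imbalance():
        return sum(q[0] for q in quotas.values()) - sum(q[1] for q in quotas.values())
    guard = 0
    while abs(imbalance()) > 1:
        d = imbalance()
        src, dst = (0, 1) if d > 0 else (1, 0)
        movable = [p for p in patients
                   if quotas[p][src] > 0 and len(pools[p][dst]) > 0
                   and len(pools[p][src]) > 0]
        if not movable:
            raise ValidationError("cannot class-balance the training draw: "
                                  "all patients carry the same single class")
        p = movable[guard % len(movable)]
        quotas[p][src] -= 1
        quotas[p][dst] += 1
        guard += 1
    idx = []
    for pid in patients:
        for pool, k in zip(pools[pid], quotas[pid]):
            if k == 0:
                continue
            idx.append(rng.choice(pool, size=k, replace=len(pool) < k))
    return np.concatenate(idx)


def _extract_rules(tree: DecisionTreeClassifier) -> list:
    t = tree.tree_
    rules = []
    node = 0
    while t.children_left[node] != -1:
        rules.append((FEATURES[t.feature[node]], "<", float(t.threshold[node])))
        # follow the child with more samples (dominant path)
        left, right = t.children_left[node], t.children_right[node]
        node = left if t.n_node_samples[left] >= t.n_node_samples[right] else right
    if not rules:
        rules.append(("none", "<", float("nan")))
    return rules


def train_threshold_tree(
    dataset: pd.DataFrame,
    max_depth: int = 2,
    n_repeats: int = 20,
    seed=None,
    sample_fraction: float = 0.85,
) -> TreeModel:
    """Repeated patient-balanced training of a depth-capped decision tree.

    Per repeat: draw the balanced training set (85% of the smallest tumor's
    pixel count per patient), fit CART on the six baseline features, and
    score balanced accuracy per patient on that patient's held-out pixels.
    Returns the model with the best mean validation BA across repeats.
    """
    rng = as_rng(seed)
    dataset = dataset.reset_index(drop=True)
    if dataset["patient_id"].nunique() < 2:
        raise ValidationError("need >= 2 patients")
    if dataset["p_responder"].nunique() < 2:
        raise ValidationError("need both classes present")
    n_per = _per_patient_sample_size(dataset, sample_fraction)
    X = dataset[FEATURES].to_numpy()
    y = dataset["p_responder"].to_numpy()
    best: Optional[TreeModel] = None
    for _ in range(n_repeats):
        train_idx = _balanced_draw(dataset, n_per, rng)
        clf = DecisionTreeClassifier(max_depth=max_depth,
                                     random_state=int(rng.integers(2 ** 31)))
        clf.fit(X[train_idx], y[train_idx])
        train_ba = classification_metrics(clf.predict(X[train_idx]),
                                          y[train_idx])["balanced_accuracy"]
        in_train = np.zeros(len(dataset), dtype=bool)
        in_train[train_idx] = True
        per_patient = {}
        for pid, sub in dataset.groupby("patient_id"):
            hold = sub.index[~in_train[sub.index]]
            if len(hold) == 0:
                continue
            m = classification_metrics(clf.predict(X[hold]), y[hold])
            per_patient[pid] = m["balanced_accuracy"]
        mean_ba = float(np.mean(list(per_patient.values()))) if per_patient else float("nan")
        model = TreeModel(rules=_extract_rules(clf), depth=int(clf.get_depth()),
                          training_ba=train_ba,
                          validation_ba_per_patient=per_patient,
                          mean_validation_ba=mean_ba, estimator=clf)
        if best is None or model.mean_validation_ba > best.mean_validation_ba:
            best = model
    return best


def lopo_evaluate(
    dataset: pd.DataFrame,
    max_depth: int = 2,
    n_repeats: int = 10,
    seed=None,
    sample_fraction: float = 0.85,
) -> dict:
    """Leave-one-patient-out cross-validation of the threshold tree.

    For each patient, trains on the remaining patients with the same
    sampling protocol and scores balanced accuracy on all of the held-out
    patient's pixels. Returns per-patient BAs (with a single-class flag
    where the held-out patient has only one class) and their mean.
    """
    rng = as_rng(seed)
    patients = sorted(dataset["patient_id"].unique())
    if len(patients) < 2:
        raise ValidationError("need >= 2 patients for leave-one-patient-out")
    per_patient, flags = {}, {}
    for pid in patients:
        hold = dataset[dataset["patient_id"] == pid]
        rest = dataset[dataset["patient_id"] != pid]
        if len(hold) == 0:
            import warnings
            warnings.warn(f"patient {pid} has no pixels; skipped")
            continue
        model = train_threshold_tree(rest, max_depth=max_depth,
                                     n_repeats=n_repeats,
                                     seed=rng.integers(2 ** 31),
                                     sample_fraction=sample_fraction)
        m = classification_metrics(model.predict(hold),
                                   hold["p_responder"].to_numpy())
        per_patient[pid] = m["balanced_accuracy"]
        flags[pid] = m["single_class"]
    return {"per_patient_ba": per_patient, "single_class": flags,
            "mean_ba": float(np.mean(list(per_patient.values())))}
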