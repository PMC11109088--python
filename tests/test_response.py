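"""VOI response statistics: medians, repeatability coefficients, responder
labels, threshold discovery, association and agreement statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qmripd.core import ParameterMap, ValidationError
from qmripd.response import (RCBand, RCSpec, ThresholdModel, build_rc_spec,
                             classification_metrics, icc_interobserver,
                             label_responders, optimize_threshold,
                             rc_from_replicates, voi_medians,
                             association_stats, RC_FACTOR)


def pmap(values, valid=None):
    values = np.asarray(values, dtype=float)
    valid = np.ones(values.shape, bool) if valid is None else valid
    return ParameterMap(values=values, units="", valid=valid)


# --- medians ---

def test_median_odd_and_even_counts():
    assert voi_medians(pmap([[[1.0, 2.0, 3.0]]]), np.ones((1, 1, 3), bool)) == 2.0
    assert voi_medians(pmap([[[1.0, 2.0, 3.0, 4.0]]]),
                       np.ones((1, 1, 4), bool)) == 2.5


def test_median_excludes_invalid_and_nan_voxels():
    values = np.array([[[1.0, np.nan, 3.0, 100.0]]])
    valid = np.array([[[True, True, True, False]]])
    assert voi_medians(pmap(values, valid), np.ones((1, 1, 4), bool)) == 2.0


def test_median_empty_mask_errors():
    with pytest.raises(ValidationError, match="T1/visitX"):
        voi_medians(pmap([[[1.0]]]), np.zeros((1, 1, 1), bool), context="T1/visitX")


# --- repeatability ---

def replicate_table(values_per_tumor):
    rows = []
    for i, vals in enumerate(values_per_tumor):
        for v in vals:
            rows.append({"patient_id": f"P{i}", "tumor_id": "T1", "median": v})
    return pd.DataFrame(rows)


def test_identical_replicates_give_zero_rc():
    res = rc_from_replicates(replicate_table([[1.0, 1.0, 1.0]]))
    assert res.per_tumor["rc"].iloc[0] == 0.0
    assert res.group_rc == 0.0


def test_unit_variance_gives_rc_2_77():
    # sample variance of {0, sqrt(2)} with ddof=1 is exactly 1
    res = rc_from_replicates(replicate_table([[0.0, np.sqrt(2.0)]]))
    assert res.per_tumor["sigma2"].iloc[0] == pytest.approx(1.0, rel=1e-12)
    assert res.per_tumor["rc"].iloc[0] == pytest.approx(2.77, rel=1e-12)


def test_rc_band_covers_95_percent_of_replicate_differences(rng):
    # 10^4 Gaussian replicate pairs; RC from the pooled variance estimate
    n = 10_000
    sigma = 0.3
    pairs = 5.0 + sigma * rng.standard_normal((n, 2))
    diffs = pairs[:, 1] - pairs[:, 0]
    sigma2_hat = np.mean(diffs ** 2) / 2.0
    rc = RC_FACTOR * np.sqrt(sigma2_hat)
    frac = np.mean(np.abs(diffs) <= rc)
    assert frac == pytest.approx(0.95, abs=0.01)


def test_no_replicates_anywhere_errors():
    with pytest.raises(ValidationError):
        rc_from_replicates(replicate_table([[1.0], [2.0]]))


def test_bland_altman_summary_on_known_pairs():
    df = replicate_table([[1.0, 1.2], [2.0, 2.6]])
    res = rc_from_replicates(df)
    diffs = np.array([0.2, 0.6])
    assert res.bland_altman.bias == pytest.approx(diffs.mean())
    sd = np.std(diffs, ddof=1)
    assert res.bland_altman.loa_upper == pytest.approx(diffs.mean() + 1.96 * sd)


# --- RC spec / bands ---

def test_literature_bands_reproduce_printed_limits():
    spec = build_rc_spec()
    lo, hi = spec.band("iauc").limits(10.0)
    assert (lo, hi) == (-3.2, 3.2)
    lo, hi = spec.band("ktrans").limits(0.10)
    assert lo == pytest.approx(-0.045)
    assert hi == pytest.approx(0.083)
    lo, hi = spec.band("t1").limits(123.0)  # absolute: baseline-independent
    assert (lo, hi) == (-0.27, 0.27)
    assert spec.band("ve").limits(0.5) == (-0.076, 0.076)
    assert spec.band("vp").limits(0.5) == (-0.0062, 0.0062)


def test_adc_band_uses_per_tumor_rc_with_group_fallback():
    per = pd.DataFrame([{"patient_id": "P1", "tumor_id": "T1", "sigma2": 1e-8,
                         "rc": 2.77e-4, "n_replicates": 3}])
    from qmripd.response import RCResult, BlandAltman
    rcres = RCResult(per_tumor=per, group_rc=2.77e-4,
                     bland_altman=BlandAltman(0.0, 0.0, 0.0, 1))
    spec = build_rc_spec(adc_rc=rcres)
    assert spec.band("adc").limits(1e-3, tumor_key=("P1", "T1"))[1] == pytest.approx(2.77e-4)
    assert spec.band("adc").limits(1e-3, tumor_key=("P9", "T9"))[1] == pytest.approx(2.77e-4)


def test_missing_rc_source_errors():
    with pytest.raises(ValidationError):
        build_rc_spec(literature={"t1": None} and {}, parameters=("t1", "bogus"))


# --- responder labels ---

def cohort_rows(param, baseline, day1):
    return pd.DataFrame([
        {"patient_id": "P1", "tumor_id": "T1", "visit": "baseline",
         "parameter": param, "median": baseline},
        {"patient_id": "P1", "tumor_id": "T1", "visit": "day1",
         "parameter": param, "median": day1},
    ])


@pytest.mark.parametrize("param,baseline,day1,expected", [
    # ADC decrease beyond RC (group fallback 0.8e-3): responder
    ("adc", 1.5e-3, 1.5e-3 - 1.1 * 0.8e-3, "P"),
    # significant but wrong direction: non-responder
    ("adc", 1.5e-3, 1.5e-3 + 1.1 * 0.8e-3, "N"),
    ("t1", 1.0, 1.0 - 0.3, "P"),
    ("t1", 1.0, 1.0 - 0.1, "N"),
    # v_e: +0.08 vs RC 0.076 is a response
    ("ve", 0.2, 0.28, "P"),
    ("ve", 0.2, 0.27, "N"),
    ("ktrans", 0.10, 0.19, "P"),   # +90% > +83%
    ("ktrans", 0.10, 0.04, "N"),   # -60% < -45%: significant, wrong direction
])
def test_direction_rule_labels(param, baseline, day1, expected):
    spec = build_rc_spec()
    out = label_responders(cohort_rows(param, baseline, day1), spec)
    lab = out[out.visit == "day1"]["label"].iloc[0]
    assert lab == expected


def test_relative_band_labels_invariant_to_rescaling():
    spec = build_rc_spec()
    a = label_responders(cohort_rows("iauc", 10.0, 14.0), spec)
    b = label_responders(cohort_rows("iauc", 1000.0, 1400.0), spec)
    assert (a[a.visit == "day1"]["label"].iloc[0]
            == b[b.visit == "day1"]["label"].iloc[0] == "P")


def test_missing_parameter_in_spec_errors():
    spec = RCSpec(bands={"t1": RCBand(band="absolute", rc=0.27,
                                      direction="decrease")})
    with pytest.raises(ValidationError):
        label_responders(cohort_rows("ve", 0.2, 0.3), spec)


# --- classification metrics ---

def test_perfect_prediction_metrics():
    m = classification_metrics(["P", "P", "N"], ["P", "P", "N"])
    assert m["sensitivity"] == m["specificity"] == m["balanced_accuracy"] == 1.0


def test_metrics_enumeration_case():
    m = classification_metrics(["PP", "PN", "PN", "PN"], ["P", "P", "N", "N"])
    assert m["sensitivity"] == 0.5
    assert m["specificity"] == 1.0
    assert m["balanced_accuracy"] == 0.75


def test_equal_discordants_mcnemar_p_is_one():
    pred = np.array([True, False, True, False])
    true = np.array([False, True, True, False])
    m = classification_metrics(pred, true)
    assert m["mcnemar_p"] == pytest.approx(1.0)


def test_single_class_flagged():
    m = classification_metrics([True, True], [True, True])
    assert m["single_class"]
    assert m["balanced_accuracy"] == 1.0  # the defined component only


def test_length_mismatch_errors():
    with pytest.raises(ValidationError):
        classification_metrics([True], [True, False])


# --- threshold optimization ---

def brute_force_best_ba(x, y, direction):
    cands = np.concatenate([[-np.inf], np.unique(x)[:-1] / 2 + np.unique(x)[1:] / 2,
                            [np.inf]])
    best = -1.0
    for c in cands:
        pred = x > c if direction == ">" else x < c
        ba = (np.sum(pred & y) / y.sum() + np.sum(~pred & ~y) / (~y).sum()) / 2
        best = max(best, ba)
    return best


def test_separable_example():
    m = optimize_threshold([1.0, 2.0, 3.0, 4.0], ["N", "N", "P", "P"], ">")
    assert m.cutpoint == pytest.approx(2.5)
    assert m.balanced_accuracy == 1.0


def test_threshold_equals_brute_force_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(4, 51))
        x = rng.normal(size=n)
        y = rng.random(n) < 0.5
        if y.all() or (~y).all():
            y[0] = ~y[0]
        d = ">" if rng.random() < 0.5 else "<"
        m = optimize_threshold(x, y, d)
        assert m.balanced_accuracy == pytest.approx(brute_force_best_ba(x, y, d))


def test_uninformative_baseline_gives_chance_ba(rng):
    x = rng.normal(size=4000)
    y = rng.random(4000) < 0.5
    m = optimize_threshold(x, y, ">")
    assert m.balanced_accuracy == pytest.approx(0.5, abs=0.05)


def test_single_class_threshold_errors():
    with pytest.raises(ValidationError):
        optimize_threshold([1.0, 2.0], ["P", "P"], ">")


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6))
def test_ba_identity_holds_for_every_model(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    x, y = rng.normal(size=n), rng.random(n) < 0.5
    if y.all() or (~y).all():
        y[0] = ~y[0]
    m = optimize_threshold(x, y, ">")
    assert m.balanced_accuracy == pytest.approx((m.sensitivity + m.specificity) / 2,
                                                abs=1e-12)


# --- null calibration ---

def test_null_cohort_flags_about_five_percent(rng):
    # no treatment effect: the RC band built from the generating sigma must
    # flag ~5% of tumors in either direction (2.77 = 1.96 sqrt(2))
    n, sigma = 500, 0.1
    spec = RCSpec(bands={"t1": RCBand(band="absolute", rc=RC_FACTOR * sigma,
                                      direction="decrease")})
    rows = []
    for i in range(n):
        base = 1.0 + sigma * rng.standard_normal()
        day1 = 1.0 + sigma * rng.standard_normal()
        rows.append({"patient_id": f"P{i}", "tumor_id": "T1", "visit": "baseline",
                     "parameter": "t1", "median": base})
        rows.append({"patient_id": f"P{i}", "tumor_id": "T1", "visit": "day1",
                     "parameter": "t1", "median": day1})
    out = label_responders(pd.DataFrame(rows), spec)
    flags = out[out.visit == "day1"]["flag"]
    frac = (flags != "within").mean()
    se = np.sqrt(0.05 * 0.95 / n)
    assert frac == pytest.approx(0.05, abs=3 * se)


# --- association ---

def test_exact_linear_change_gives_r_squared_one(rng):
    rows = []
    for i, b in enumerate(np.linspace(1.0, 2.0, 8)):
        rows.append({"patient_id": f"P{i}", "tumor_id": "T1", "visit": "baseline",
                     "parameter": "t1", "median": b})
        rows.append({"patient_id": f"P{i}", "tumor_id": "T1", "visit": "day1",
                     "parameter": "t1", "median": b + (-0.5 * b + 0.1)})
    spec = build_rc_spec()
    out = label_responders(pd.DataFrame(rows), spec)
    stats = association_stats(out)
    reg = stats["regression"].set_index("parameter").loc["t1"]
    assert reg["r_squared"] == pytest.approx(1.0)
    assert reg["slope"] == pytest.approx(-0.5)


def test_identical_changes_correlate_perfectly(rng):
    rows = []
    for i in range(6):
        d = rng.normal()
        for p in ("t1", "ve"):
            rows.append({"patient_id": f"P{i}", "tumor_id": "T1",
                         "visit": "baseline", "parameter": p, "median": 1.0})
            rows.append({"patient_id": f"P{i}", "tumor_id": "T1",
                         "visit": "day1", "parameter": p, "median": 1.0 + d})
    spec = build_rc_spec()
    out = label_responders(pd.DataFrame(rows), spec)
    corr = association_stats(out)["change_correlations"]
    assert corr["r"].iloc[0] == pytest.approx(1.0)


# --- ICC ---

def icc2_anova_oracle(a, b):
    """Two-way random, absolute agreement, single measures, via the
    classical mean squares."""
    n, k = a.size, 2
    x = np.stack([a, b], axis=1)
    grand = x.mean()
    ms_r = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    ms_e = (np.sum((x - x.mean(axis=1, keepdims=True)
                    - x.mean(axis=0, keepdims=True) + grand) ** 2)
            / ((n - 1) * (k - 1)))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


def test_identical_observers_give_icc_one():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    res = icc_interobserver(a, a.copy())
    assert res[res.visit == "overall"]["icc"].iloc[0] == pytest.approx(1.0)


def test_independent_observers_give_icc_near_zero(rng):
    a, b = rng.normal(size=400), rng.normal(size=400)
    res = icc_interobserver(a, b)
    assert abs(res[res.visit == "overall"]["icc"].iloc[0]) < 0.15


def test_offset_observer_matches_anova_oracle():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = a + 0.8
    res = icc_interobserver(a, b)
    got = res[res.visit == "overall"]["icc"].iloc[0]
    assert got == pytest.approx(icc2_anova_oracle(a, b), rel=1e-6)
    assert got < 1.0  # absolute agreement penalizes the fixed offset
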