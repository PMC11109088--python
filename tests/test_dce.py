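"""Concentration conversion, AIF handling, iAUC and the extended Tofts
model (forward and inverse)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qmripd.core import AIF, ImageSeries, ParameterMap, ValidationError, spgr_signal
from qmripd.dce import (ConcentrationSeries, analytic_aif, compute_iauc,
                        detect_injection, extract_aif, fit_extended_tofts,
                        signal_to_concentration, tofts_forward)


def conc_series(curves, times, injection_frame=0):
    curves = np.atleast_2d(curves)
    return ConcentrationSeries(conc_mM=curves, times_s=times,
                               injection_frame=injection_frame,
                               r1_per_mM_s=4.5,
                               valid=np.ones(curves.shape[0], bool),
                               clipped_negative=np.zeros(curves.shape[0], bool))


# --- injection detection ---

def test_planted_step_detected():
    data = np.ones((2, 2, 1, 20))
    data[..., 8:] = 2.0
    s = ImageSeries(data=data, kind="dce", frame_times_s=np.arange(20) * 8.0)
    idx, baseline = detect_injection(s)
    assert idx == 8
    np.testing.assert_array_equal(baseline, np.arange(8))


def test_override_short_circuits_detection():
    data = np.ones((1, 1, 1, 10))
    s = ImageSeries(data=data, kind="dce", frame_times_s=np.arange(10) * 8.0)
    idx, baseline = detect_injection(s, override=6)
    assert idx == 6 and baseline.size == 6


def test_flat_series_without_override_errors():
    data = np.ones((1, 1, 1, 10))
    s = ImageSeries(data=data, kind="dce", frame_times_s=np.arange(10) * 8.0)
    with pytest.raises(ValidationError, match="no enhancement"):
        detect_injection(s)


# --- signal -> concentration ---

def spgr_dyn_series(t1_t, t1_pre_s=1.0, m0=1000.0, fa=30.0, tr=3.0, n_base=3):
    """Dynamic series with baseline frames at t1_pre then frames at t1_t."""
    t1s = [t1_pre_s] * n_base + list(t1_t)
    sig = np.array([spgr_signal(t, m0, fa, tr) for t in t1s])
    data = sig.reshape(1, 1, 1, -1)
    return ImageSeries(data=data, kind="dce", flip_angle_deg=fa, tr_ms=tr,
                       frame_times_s=np.arange(len(t1s)) * 8.0)


def test_unchanged_t1_gives_zero_concentration():
    s = spgr_dyn_series([1.0, 1.0])
    t1_pre = ParameterMap(values=np.full((1, 1, 1), 1.0), units="s",
                          valid=np.ones((1, 1, 1), bool))
    conc = signal_to_concentration(s, t1_pre, 4.5, baseline_frames=np.arange(3))
    np.testing.assert_allclose(conc.conc_mM, 0.0, atol=1e-10)


def test_concentration_closed_form_half_t1():
    # 1/0.5 - 1/1.0 = 1.0 s^-1; / 4.5 = 0.2222 mM
    s = spgr_dyn_series([0.5])
    t1_pre = ParameterMap(values=np.full((1, 1, 1), 1.0), units="s",
                          valid=np.ones((1, 1, 1), bool))
    conc = signal_to_concentration(s, t1_pre, 4.5, baseline_frames=np.arange(3))
    assert conc.conc_mM[0, 0, 0, -1] == pytest.approx(1.0 / 4.5, rel=1e-9)


def test_invalid_relaxivity_or_angle_rejected():
    s = spgr_dyn_series([0.5])
    t1_pre = ParameterMap(values=np.full((1, 1, 1), 1.0), units="s",
                          valid=np.ones((1, 1, 1), bool))
    with pytest.raises(ValidationError):
        signal_to_concentration(s, t1_pre, -1.0, baseline_frames=np.arange(3))
    with pytest.raises(ValidationError):
        signal_to_concentration(s, t1_pre, 4.5, flip_angle_deg=120.0,
                                baseline_frames=np.arange(3))


# --- AIF extraction ---

def test_identical_artery_voxels_return_their_curve():
    t = np.arange(10) * 8.0
    curve = np.linspace(0, 2, 10)
    curves = np.tile(curve, (5, 1))
    conc = conc_series(curves, t)
    mask = np.ones(5, bool)
    aif = extract_aif(conc, mask, top_k=None)
    np.testing.assert_allclose(aif.cp_mM, curve)


def test_top_k_selection_by_peak():
    t = np.arange(5) * 8.0
    curves = np.array([[0, 1, 1, 0.5, 0.2],
                       [0, 2, 2, 1.0, 0.4],
                       [0, 3, 3, 1.5, 0.6]], dtype=float)
    conc = conc_series(curves, t)
    aif = extract_aif(conc, np.ones(3, bool), top_k=2)
    np.testing.assert_allclose(aif.cp_mM, curves[1:].mean(axis=0))


def test_hematocrit_correction_scales_blood_to_plasma():
    t = np.arange(5) * 8.0
    curve = np.array([[0.0, 1.0, 2.0, 1.0, 0.5]])
    conc = conc_series(curve, t)
    aif = extract_aif(conc, np.ones(1, bool), hematocrit=0.45)
    np.testing.assert_allclose(aif.cp_mM, curve[0] / 0.55)


def test_empty_artery_mask_rejected():
    conc = conc_series(np.zeros((2, 5)), np.arange(5) * 8.0)
    with pytest.raises(ValidationError):
        extract_aif(conc, np.zeros(2, bool))


# --- iAUC ---

def test_iauc_constant_curve():
    t = np.arange(0, 200.0, 8.0)
    conc = conc_series(np.full((1, t.size), 0.1), t)
    assert compute_iauc(conc, 90.0).values[0] == pytest.approx(9.0, rel=1e-9)


def test_iauc_zero_curve():
    t = np.arange(0, 200.0, 8.0)
    conc = conc_series(np.zeros((1, t.size)), t)
    assert compute_iauc(conc, 90.0).values[0] == 0.0


def test_iauc_ramp_closed_form():
    t = np.arange(0, 200.0, 8.0)
    conc = conc_series(0.001 * t[None, :], t)
    assert compute_iauc(conc, 90.0).values[0] == pytest.approx(4.05, rel=1e-9)


def test_iauc_window_beyond_acquisition_rejected():
    t = np.arange(0, 60.0, 8.0)
    conc = conc_series(np.zeros((1, t.size)), t)
    with pytest.raises(ValidationError):
        compute_iauc(conc, 90.0)


# --- Tofts forward ---

def test_forward_zero_parameters_give_zero_curve(step_aif):
    ct = tofts_forward(0.0, 0.2, 0.0, step_aif)
    np.testing.assert_allclose(ct, 0.0, atol=1e-15)


def test_forward_pure_vascular_term(step_aif):
    ct = tofts_forward(0.0, 0.2, 0.05, step_aif)
    np.testing.assert_allclose(ct, 0.05 * step_aif.cp_mM, rtol=1e-12)


def test_forward_step_aif_closed_form():
    t = np.arange(0, 3000.0, 8.0)  # long enough to reach the plateau
    aif = AIF(times_s=t, cp_mM=np.ones_like(t))
    kt, ve = 0.07, 0.17
    ct = tofts_forward(kt, ve, 0.0, aif)
    t_min = t / 60.0
    expected = ve * (1.0 - np.exp(-(kt / ve) * t_min))
    np.testing.assert_allclose(ct, expected, rtol=1e-9)
    assert ct[-1] == pytest.approx(ve, rel=0.01)  # plateau at v_e


def test_forward_undefined_rate_rejected(step_aif):
    with pytest.raises(ValidationError):
        tofts_forward(0.1, 0.0, 0.0, step_aif)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(scale=st.floats(min_value=0.1, max_value=10.0))
def test_forward_linear_in_aif(scale):
    t = np.arange(0, 400.0, 8.0)
    aif1 = analytic_aif(t, 40.0)
    aif2 = AIF(times_s=t, cp_mM=aif1.cp_mM * scale)
    c1 = tofts_forward(0.1, 0.3, 0.02, aif1)
    c2 = tofts_forward(0.1, 0.3, 0.02, aif2)
    np.testing.assert_allclose(c2, scale * c1, rtol=1e-9)


def test_forward_iauc_monotone_in_ktrans_and_ve(step_aif):
    t = step_aif.times_s

    def iauc_of(kt, ve):
        ct = tofts_forward(kt, ve, 0.0, step_aif)
        return compute_iauc(conc_series(ct, t), 90.0).values[0]

    kts = [0.02, 0.05, 0.1, 0.3]
    vals = [iauc_of(k, 0.3) for k in kts]
    assert np.all(np.diff(vals) > 0)
    ves = [0.1, 0.2, 0.4]
    vals = [iauc_of(0.1, v) for v in ves]
    assert np.all(np.diff(vals) > 0)


# --- Tofts inverse ---

def test_fit_recovers_parameter_grid_noiselessly():
    t = np.arange(0, 400.0, 8.0)
    aif = analytic_aif(t, 40.0)
    kt, ve, vp = np.meshgrid([0.02, 0.07, 0.3], [0.1, 0.17, 0.5],
                             [0.005, 0.02, 0.05], indexing="ij")
    kt, ve, vp = kt.ravel(), ve.ravel(), vp.ravel()
    curves = tofts_forward(kt, ve, vp, aif)
    fit = fit_extended_tofts(curves, aif)
    np.testing.assert_allclose(fit.ktrans_per_min, kt, rtol=0.01)
    np.testing.assert_allclose(fit.ve, ve, rtol=0.01)
    np.testing.assert_allclose(fit.vp, vp, rtol=0.01)


def test_fit_zero_curve_degenerate():
    t = np.arange(0, 400.0, 8.0)
    aif = analytic_aif(t, 40.0)
    fit = fit_extended_tofts(np.zeros((1, t.size)), aif)
    assert fit.ktrans_per_min[0] == 0.0
    assert fit.vp[0] == 0.0
    assert not fit.valid[0]  # v_e undefined on a zero curve


def test_fit_on_standard_tofts_data_returns_near_zero_vp():
    t = np.arange(0, 400.0, 8.0)
    aif = analytic_aif(t, 40.0)
    curves = tofts_forward(np.array([0.1]), np.array([0.3]), np.array([0.0]), aif)
    fit = fit_extended_tofts(curves, aif)
    assert fit.vp[0] == pytest.approx(0.0, abs=1e-4)
    assert fit.ktrans_per_min[0] == pytest.approx(0.1, rel=0.01)


def test_fit_residual_not_above_any_multistart_initialization(rng):
    t = np.arange(0, 400.0, 8.0)
    aif = analytic_aif(t, 40.0)
    curve = tofts_forward(0.1, 0.3, 0.02, aif)
    noisy = curve + 0.01 * rng.standard_normal(curve.shape)
    refined = fit_extended_tofts(noisy, aif, refine=True)
    grid_only = fit_extended_tofts(noisy, aif, refine=False)
    assert refined.residual[0] <= grid_only.residual[0] + 1e-12


def test_noisy_fit_median_bias_within_ten_percent(rng):
    t = np.arange(0, 400.0, 8.0)
    aif = analytic_aif(t, 40.0)
    kt, ve, vp = 0.07, 0.17, 0.02
    clean = tofts_forward(kt, ve, vp, aif)
    peak = clean.max()
    curves = np.tile(clean, (100, 1)) + (peak / 20.0) * rng.standard_normal((100, t.size))
    fit = fit_extended_tofts(np.clip(curves, 0, None), aif)
    assert np.median(fit.ktrans_per_min) == pytest.approx(kt, rel=0.10)
    assert np.median(fit.ve) == pytest.approx(ve, rel=0.10)
    assert np.median(fit.vp) == pytest.approx(vp, abs=0.01)
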