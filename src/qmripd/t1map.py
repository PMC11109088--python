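"""Variable-flip-angle T1 mapping from spoiled gradient-echo images.

The SPGR steady-state signal S(a) = M0 sin(a)(1 - E1)/(1 - cos(a) E1), with
E1 = exp(-TR/T1), is linear in the (S/sin a, S/tan a) plane: S/sin a =
E1 * S/tan a + M0 (1 - E1). That linearization provides the initial
estimate, which is then refined by a damped Gauss-Newton minimization of the
nonlinear residual, vectorized over all voxels; the damping (step halving)
guarantees the refinement never increases the residual relative to the
initialization. Optional utilities estimate per-image intensity-scale
factors (when images in the series were reconstructed with inconsistent
scaling) and paint reference T1 values by tissue label when a multi-angle
acquisition is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ImageSeries, ParameterMap, ValidationError, spgr_signal

__all__ = ["T1Fit", "ReferenceT1Table", "estimate_intensity_scales",
           "fit_t1_vfa", "assign_reference_t1"]

#: physiological T1 bounds at ~1.5 T plus numerical safety margin, seconds
T1_BOUNDS = (0.05, 10.0)


@dataclass
class T1Fit:
    t1: np.ndarray  # s
    m0: np.ndarray
    valid: np.ndarray
    scale_factors: np.ndarray
    smoothing_sigma: Optional[float] = None
    clipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def t1_map(self) -> ParameterMap:
        return ParameterMap(values=self.t1, units="s", valid=self.valid, name="t1")


@dataclass
class ReferenceT1Table:
    """Literature T1 per tissue label at a stated field strength.

    The shipped defaults are implementation defaults for a 1.5 T abdominal
    protocol, not measured values; override them per study.
    """

    values_s: dict  # label (int) -> T1 in seconds
    field_strength_T: float = 1.5

    def __post_init__(self) -> None:
        for k, v in self.values_s.items():
            if v <= 0:
                raise ValidationError(f"reference T1 for label {k} must be > 0")


def _linearized_t1(data: np.ndarray, fas_rad: np.ndarray, tr_ms: float):
    """Per-voxel (T1, M0) from the S/sin-vs-S/tan regression."""
    y = data / np.sin(fas_rad)
    x = data / np.tan(fas_rad)
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=-1)
    sxy = np.sum((x - xm) * (y - ym), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = sxy / sxx
        intercept = ym[..., 0] - e1 * xm[..., 0]
        m0 = intercept / (1.0 - e1)
        t1 = -(tr_ms / 1000.0) / np.log(e1)
    return t1, m0, e1


def _residual_norm(data, fas_deg, tr_ms, t1, m0):
    pred = np.stack([spgr_signal(t1, m0, fa, tr_ms) for fa in fas_deg], axis=-1)
    return np.sum((pred - data) ** 2, axis=-1)


def fit_t1_vfa(
    series: ImageSeries,
    scale_factors: Optional[np.ndarray] = None,
    smoothing_sigma: Optional[float] = None,
    bounds: tuple[float, float] = T1_BOUNDS,
    fa_scale_map: Optional[np.ndarray] = None,
    n_iter: int = 30,
) -> T1Fit:
    """Fit T1 and M0 maps from a multi-flip-angle SPGR series.

    ``scale_factors`` divides each image before fitting (see
    :func:`estimate_intensity_scales`). ``smoothing_sigma`` optionally
    Gaussian-smooths each angle image in-plane before the voxelwise fit — a
    simple spatial-regularization surrogate, off by default.
    ``fa_scale_map`` is a per-voxel multiplicative correction to the nominal
    flip angles (e.g. from an external B1 map). Out-of-bounds T1 solutions
    are clipped and flagged.
    """
    fas = series.flip_angles_deg
    tr_ms = series.tr_ms
    if fas is None or np.unique(fas).size < 2:
        raise ValidationError(
            f"series {series.series_id!r}: T1 map cannot be obtained, the "
            "series was acquired with one flip angle only")
    if tr_ms is None or tr_ms <= 0:
        raise ValidationError("TR must be positive")
    data = series.data.astype(float)
    if scale_factors is not None:
        scale_factors = np.asarray(scale_factors, dtype=float)
        if scale_factors.size != data.shape[-1] or np.any(scale_factors <= 0):
            raise ValidationError("need one positive scale factor per image")
        data = data / scale_factors
    if smoothing_sigma:
        data = np.stack(
            [gaussian_filter(data[..., i], sigma=(smoothing_sigma, smoothing_sigma, 0))
             for i in range(data.shape[-1])], axis=-1)

    valid = np.all(data > 0, axis=-1)
    if fa_scale_map is None:
        fas_rad = np.deg2rad(fas)[None, None, None, :] * np.ones(data.shape[:3] + (1,))
    else:
        fas_rad = np.deg2rad(fas)[None, None, None, :] * np.asarray(fa_scale_map)[..., None]

    t1, m0, e1 = _linearized_t1(np.where(valid[..., None], data, 1.0), fas_rad, tr_ms)
    lin_ok = valid & np.isfinite(t1) & np.isfinite(m0) & (m0 > 0) & (e1 > 0) & (e1 < 1)
    # where the linearization fails (noise or inconsistent scaling), start
    # from a nominal T1 with M0 matched to the first angle's signal
    good = valid.copy()
    t1_init = np.clip(np.where(lin_ok, t1, 1.0), *bounds)
    f0 = spgr_signal(t1_init, 1.0, np.rad2deg(fas_rad[..., 0]), tr_ms)
    with np.errstate(divide="ignore", invalid="ignore"):
        m0_fallback = np.where(f0 > 0, data[..., 0] / np.where(f0 > 0, f0, 1.0), 1.0)
    m0_init = np.where(lin_ok, np.abs(m0), np.maximum(m0_fallback, 1e-12))

    # damped Gauss-Newton refinement, vectorized over voxels
    fas_deg_eff = np.rad2deg(fas_rad)
    t1_cur, m0_cur = t1_init.copy(), m0_init.copy()

    def rnorm(t1v, m0v):
        pred = spgr_signal(t1v[..., None], m0v[..., None], fas_deg_eff, tr_ms)
        return np.sum((pred - data) ** 2, axis=-1)

    res_cur = rnorm(t1_cur, m0_cur)
    tr_s = tr_ms / 1000.0
    for _ in range(n_iter):
        e1v = np.exp(-tr_s / t1_cur)[..., None]
        sin_a, cos_a = np.sin(fas_rad), np.cos(fas_rad)
        denom = 1.0 - cos_a * e1v
        f = sin_a * (1.0 - e1v) / denom
        pred = m0_cur[..., None] * f
        r = pred - data
        # d pred / d E1 and chain to T1
        dS_dE1 = m0_cur[..., None] * sin_a * (cos_a - 1.0) / denom ** 2
        dE1_dT1 = (tr_s / t1_cur ** 2)[..., None] * e1v
        j1 = dS_dE1 * dE1_dT1
        j2 = f
        a11 = np.sum(j1 * j1, axis=-1)
        a12 = np.sum(j1 * j2, axis=-1)
        a22 = np.sum(j2 * j2, axis=-1)
        b1 = -np.sum(j1 * r, axis=-1)
        b2 = -np.sum(j2 * r, axis=-1)
        det = a11 * a22 - a12 * a12
        with np.errstate(divide="ignore", invalid="ignore"):
            dt1 = np.where(det > 1e-300, (a22 * b1 - a12 * b2) / det, 0.0)
            dm0 = np.where(det > 1e-300, (a11 * b2 - a12 * b1) / det, 0.0)
        step = np.ones_like(t1_cur)
        improved = np.zeros_like(good)
        t1_new, m0_new = t1_cur.copy(), m0_cur.copy()
        for _halve in range(8):
            trial_t1 = np.clip(t1_cur + step * dt1, *bounds)
            trial_m0 = np.maximum(m0_cur + step * dm0, 1e-12)
            res_trial = rnorm(trial_t1, trial_m0)
            accept = good & ~improved & (res_trial <= res_cur)
            t1_new[accept] = trial_t1[accept]
            m0_new[accept] = trial_m0[accept]
            res_cur = np.where(accept, res_trial, res_cur)
            improved |= accept
            step *= 0.5
            if improved[good].all():
                break
        t1_cur, m0_cur = t1_new, m0_new

    clipped = good & ((t1_cur <= bounds[0] + 1e-12) | (t1_cur >= bounds[1] - 1e-12))
    t1_out = np.where(good, t1_cur, np.nan)
    m0_out = np.where(good, m0_cur, np.nan)
    if scale_factors is None:
        scale_factors = np.ones(data.shape[-1])
    return T1Fit(t1=t1_out, m0=m0_out, valid=good, scale_factors=scale_factors,
                 smoothing_sigma=smoothing_sigma, clipped=clipped)


def estimate_intensity_scales(
    series: ImageSeries,
    reference_mask: np.ndarray,
    max_voxels: int = 400,
) -> np.ndarray:
    """Estimate per-image intensity-scale factors of a multi-angle series.

    Model: data_i = s_i * SPGR(T1, M0, a_i), with the first image the unit
    reference (s_0 = 1). The free log-scales are found by nonlinear least
    squares on reference-region voxels with the per-voxel (T1, M0) fit
    nested inside (variable projection): at the true factors a consistent
    series is fit exactly, so the outer residual vanishes. Dividing the
    series by the returned factors restores consistency with a single M0.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not np.any(reference_mask):
        raise ValidationError("reference mask is empty")
    if series.n_volumes < 2:
        raise ValidationError("need >= 2 images to estimate scale factors")
    curves = series.data[reference_mask]  # (V, n_img)
    curves = curves[np.all(curves > 0, axis=1)]
    if curves.shape[0] == 0:
        raise ValidationError("no voxel in the reference mask has positive "
                              "signal at every flip angle")
    if curves.shape[0] > max_voxels:
        idx = np.linspace(0, curves.shape[0] - 1, max_voxels).astype(int)
        curves = curves[idx]
    sub = ImageSeries(data=curves[:, None, None, :], kind=series.kind,
                      flip_angles_deg=series.flip_angles_deg, tr_ms=series.tr_ms)
    norm = float(np.median(curves))
    from dataclasses import replace as _replace
    from scipy.optimize import least_squares as _lsq

    def resid(log_s: np.ndarray) -> np.ndarray:
        scales = np.concatenate([[1.0], np.exp(log_s)])
        fit = fit_t1_vfa(_replace(sub, data=sub.data / scales), n_iter=15)
        pred = np.stack([spgr_signal(fit.t1, fit.m0, fa, series.tr_ms)
                         for fa in series.flip_angles_deg], axis=-1)
        r = (pred - sub.data / scales) / norm
        return r[fit.valid].ravel() if np.any(fit.valid) else np.full(8, 1e3)

    sol = _lsq(resid, np.zeros(series.n_volumes - 1), method="lm",
               xtol=1e-12, ftol=1e-12)
    return np.concatenate([[1.0], np.exp(sol.x)])


def assign_reference_t1(
    label_map: np.ndarray,
    table: ReferenceT1Table,
    overrides: Optional[dict] = None,
) -> ParameterMap:
    """Piecewise-constant T1 map from literature values by tissue label.

    ``overrides`` (label -> T1 s) shadows table entries. Every nonzero label
    present in ``label_map`` must be covered, else an error lists the gap.
    """
    label_map = np.asarray(label_map)
    values = dict(table.values_s)
    if overrides:
        values.update(overrides)
    present = [int(l) for l in np.unique(label_map) if l != 0]
    missing = [l for l in present if l not in values]
    if missing:
        raise ValidationError(f"labels {missing} have no reference T1 entry")
    t1 = np.zeros(label_map.shape, dtype=float)
    for lab in present:
        t1[label_map == lab] = values[lab]
    valid = label_map != 0
    t1[~valid] = np.nan
    return ParameterMap(values=t1, units="s", valid=valid, name="t1")
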