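"""Dynamic contrast-enhanced MRI: concentration conversion, AIF handling,
iAUC, and the extended Tofts compartment model.

The extended Tofts model describes the tissue gadolinium concentration as

    C_t(t) = v_p C_p(t) + k^trans \\int_0^t C_p(u) exp(-(k^trans/v_e)(t-u)) du

with k^trans the plasma-to-interstitium transfer constant (min^-1), v_e the
extravascular extracellular volume fraction and v_p the plasma volume
fraction. The convolution is evaluated with an exponential-kernel recursion
that is exact for a piecewise-linear C_p, which keeps it stable at the
~8 s frame spacing of typical dynamic protocols.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import AIF, ImageSeries, ParameterMap, ValidationError, spgr_signal

__all__ = [
    "ConcentrationSeries",
    "PKMaps",
    "analytic_aif",
    "detect_injection",
    "signal_to_concentration",
    "extract_aif",
    "compute_iauc",
    "tofts_forward",
    "fit_extended_tofts",
]

#: fitting bounds: k^trans (min^-1), v_e (fraction), v_p (fraction)
KTRANS_BOUNDS = (0.0, 5.0)
VE_BOUNDS = (1e-6, 1.0)
VP_BOUNDS = (0.0, 1.0)


@dataclass
class ConcentrationSeries:
    """Voxelwise gadolinium concentration C(t) in mM on the frame grid."""

    conc_mM: np.ndarray  # (..., n_frames)
    times_s: np.ndarray
    injection_frame: int
    r1_per_mM_s: float
    valid: np.ndarray  # (...,) voxels where the conversion succeeded
    clipped_negative: np.ndarray  # (...,) voxels where negative C was clipped

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValidationError("frame time grid must be strictly increasing")

    @property
    def injection_time_s(self) -> float:
        return float(self.times_s[self.injection_frame])


@dataclass
class PKMaps:
    """Extended-Tofts parameter maps with per-voxel fit diagnostics."""

    ktrans_per_min: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    valid: np.ndarray


def analytic_aif(
    times_s: np.ndarray,
    injection_time_s: float,
    amp1_mM: float = 5.0,
    decay1_per_min: float = 3.0,
    amp2_mM: float = 1.0,
    decay2_per_min: float = 0.3,
    rise_per_min: float = 25.0,
) -> AIF:
    """Biexponential-with-bolus plasma input function.

    Cp(t) = (a1 e^{-m1 tau} + a2 e^{-m2 tau}) (1 - e^{-m3 tau}) for
    tau = t - t_inj >= 0 in minutes, zero before injection. The defaults give
    a first-pass peak of ~4 mM ~6 s after injection washing out to ~0.2 mM by
    5 min, a realistic shape for a power-injected bolus.
    """
    times_s = np.asarray(times_s, dtype=float)
    tau_min = np.maximum(times_s - injection_time_s, 0.0) / 60.0
    cp = (amp1_mM * np.exp(-decay1_per_min * tau_min)
          + amp2_mM * np.exp(-decay2_per_min * tau_min)) * (
              1.0 - np.exp(-rise_per_min * tau_min))
    cp[times_s < injection_time_s] = 0.0
    return AIF(times_s=times_s, cp_mM=cp, source="analytic")


# ---------------------------------------------------------------------------
# bolus arrival
# ---------------------------------------------------------------------------

def detect_injection(
    series: ImageSeries,
    artery_mask: Optional[np.ndarray] = None,
    override: Optional[int] = None,
    rel_threshold: float = 0.05,
    min_baseline_frames: int = 3,
) -> tuple[int, np.ndarray]:
    """Locate the first post-bolus frame of a dynamic series.

    Returns ``(injection_frame, baseline_frame_indices)`` where baseline
    frames are all frames strictly before the detected frame. Detection uses
    the mean signal inside ``artery_mask`` (or over all nonzero voxels): the
    first frame exceeding the running-baseline mean by ``rel_threshold``
    relative enhancement, sustained on the following frame.
    """
    if override is not None:
        if not 0 < override < series.n_volumes:
            raise ValidationError("injection override outside the frame range")
        return int(override), np.arange(int(override))
    if series.n_volumes < 3:
        raise ValidationError("need >= 3 frames to detect the bolus")
    data = series.data
    if artery_mask is not None:
        if not np.any(artery_mask):
            raise ValidationError("artery mask is empty")
        curve = data[artery_mask].mean(axis=0)
    else:
        body = np.any(data > 0, axis=-1)
        if not np.any(body):
            raise ValidationError("series contains no signal")
        curve = data[body].mean(axis=0)
    for j in range(min_baseline_frames, series.n_volumes):
        base = curve[:j].mean()
        thr = base * (1.0 + rel_threshold)
        if curve[j] > thr and (j + 1 >= curve.size or curve[j + 1] > thr):
            return j, np.arange(j)
    raise ValidationError("no enhancement detected and no injection override given")


# ---------------------------------------------------------------------------
# signal -> concentration
# ---------------------------------------------------------------------------

def signal_to_concentration(
    series: ImageSeries,
    t1_pre: ParameterMap,
    r1_per_mM_s: float,
    flip_angle_deg: Optional[float] = None,
    tr_ms: Optional[float] = None,
    baseline_frames: Optional[np.ndarray] = None,
) -> ConcentrationSeries:
    """Convert a dynamic SPGR series into gadolinium concentration.

    M0 is normalized per voxel from the mean pre-injection signal and the
    pre-contrast T1; each frame's signal is then inverted through the SPGR
    equation to T1(t), and C(t) = (1/T1(t) - 1/T1(0)) / r1. Negative
    concentrations are clipped to zero and flagged. Frames before injection
    are zero by construction.
    """
    fa = series.flip_angle_deg if flip_angle_deg is None else flip_angle_deg
    tr = series.tr_ms if tr_ms is None else tr_ms
    if fa is None or not 0.0 < fa <= 90.0:
        raise ValidationError("dynamic flip angle must be in (0, 90] degrees")
    if tr is None or tr <= 0:
        raise ValidationError("TR must be positive")
    if r1_per_mM_s <= 0:
        raise ValidationError("relaxivity must be positive")
    if baseline_frames is None:
        if series.injection_frame is None:
            raise ValidationError("baseline frames unknown: give baseline_frames "
                                  "or a series with injection_frame set")
        baseline_frames = np.arange(series.injection_frame)
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    if baseline_frames.size == 0:
        raise ValidationError("baseline frame set is empty")
    injection_frame = int(baseline_frames.max() + 1)

    data = series.data
    t1_0 = t1_pre.masked()
    s_base = data[..., baseline_frames].mean(axis=-1)
    unit = spgr_signal(t1_0, 1.0, fa, tr)
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = s_base / unit
    valid = t1_pre.valid & np.isfinite(m0) & (s_base > 0)

    a = np.deg2rad(fa)
    sin_a, cos_a = np.sin(a), np.cos(a)
    m0s = m0[..., None] * sin_a
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (data - m0s) / (data * cos_a - m0s)
    ok = valid[..., None] & (e1 > 0) & (e1 < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1_t = np.where(ok, -(tr / 1000.0) / np.log(np.where(ok, e1, 0.5)), np.nan)
        conc = (1.0 / t1_t - 1.0 / t1_0[..., None]) / r1_per_mM_s
    conc[..., :injection_frame] = 0.0
    clipped = np.any(conc < 0, axis=-1)
    conc = np.clip(conc, 0.0, None)
    valid = valid & np.all(np.isfinite(conc), axis=-1)
    conc[~valid] = np.nan

    times = series.frame_times_s
    if times is None:
        raise ValidationError("dynamic series lacks frame times")
    return ConcentrationSeries(conc_mM=conc, times_s=times,
                               injection_frame=injection_frame,
                               r1_per_mM_s=float(r1_per_mM_s),
                               valid=valid, clipped_negative=clipped)


# ---------------------------------------------------------------------------
# AIF extraction and iAUC
# ---------------------------------------------------------------------------

def extract_aif(conc: ConcentrationSeries, artery_mask: np.ndarray,
                top_k: Optional[int] = 10,
                hematocrit: Optional[float] = None) -> AIF:
    """Average selected artery-voxel concentration curves into an AIF.

    Selection keeps the ``top_k`` voxels by peak concentration (all voxels if
    ``top_k`` is None or exceeds the mask size). ``hematocrit`` optionally
    converts the whole-blood curve to plasma concentration by 1/(1 - Hct);
    the default applies no correction.
    """
    artery_mask = np.asarray(artery_mask, dtype=bool)
    if not np.any(artery_mask):
        raise ValidationError("artery mask is empty")
    curves = conc.conc_mM[artery_mask & conc.valid]
    if curves.size == 0:
        raise ValidationError("no valid artery voxels to extract an AIF from")
    if top_k is not None and top_k < curves.shape[0]:
        peaks = np.nanmax(curves, axis=1)
        keep = np.argsort(peaks)[-top_k:]
        curves = curves[keep]
    cp = curves.mean(axis=0)
    if hematocrit is not None:
        if not 0.0 <= hematocrit < 1.0:
            raise ValidationError("hematocrit must be in [0, 1)")
        cp = cp / (1.0 - hematocrit)
    return AIF(times_s=conc.times_s, cp_mM=cp,
               source="measured-from-artery", hematocrit=hematocrit)


def compute_iauc(conc: ConcentrationSeries, window_s: float = 90.0) -> ParameterMap:
    """Initial area under the concentration curve over ``window_s`` seconds
    from injection time (trapezoidal, linear interpolation at the window
    edge). Units mM*s."""
    t0 = conc.injection_time_s
    t_end = t0 + window_s
    times = conc.times_s
    if t_end > times[-1] + 1e-9:
        raise ValidationError(
            f"iAUC window of {window_s} s extends beyond the acquisition "
            f"({times[-1] - t0:.1f} s available after injection)")
    # augmented grid with an interpolated sample exactly at the window edge
    inside = (times >= t0 - 1e-12) & (times <= t_end + 1e-12)
    t_in = times[inside]
    flat = conc.conc_mM.reshape(-1, times.size)
    c_in = flat[:, inside]
    if t_in.size == 0 or t_in[-1] < t_end - 1e-9:
        c_edge = np.array([np.interp(t_end, times, c) for c in flat])
        t_in = np.append(t_in, t_end)
        c_in = np.concatenate([c_in, c_edge[:, None]], axis=1)
    iauc = np.trapezoid(c_in, t_in, axis=1)
    iauc = iauc.reshape(conc.conc_mM.shape[:-1])
    return ParameterMap(values=iauc, units="mM*s",
                        valid=conc.valid & np.isfinite(iauc), name="iauc")


# ---------------------------------------------------------------------------
# extended Tofts forward model
# ---------------------------------------------------------------------------

def _exp_conv(cp: np.ndarray, times_s: np.ndarray, kep_per_s: np.ndarray) -> np.ndarray:
    """I(t_n) = int_0^{t_n} Cp(u) exp(-kep (t_n - u)) du for piecewise-linear
    Cp, exactly, via the segmentwise recursion. ``kep_per_s`` broadcasts over
    voxels: shape (V,) -> output (V, T)."""
    kep = np.atleast_1d(np.asarray(kep_per_s, dtype=float))[:, None]  # (V,1)
    dt = np.diff(times_s)  # (T-1,)
    out = np.zeros((kep.shape[0], times_s.size))
    upper = np.zeros(kep.shape[0])
    for n in range(1, times_s.size):
        d = dt[n - 1]
        c0, c1 = cp[n - 1], (cp[n] - cp[n - 1]) / d
        kd = kep[:, 0] * d
        small = kd < 1e-8
        with np.errstate(divide="ignore", invalid="ignore"):
            em = np.exp(-kd)
            g0 = np.where(small, d, (1.0 - em) / kep[:, 0])
            g1 = np.where(small, d * d / 2.0, d / kep[:, 0] - (1.0 - em) / kep[:, 0] ** 2)
        upper = upper * np.exp(-kd) + c0 * g0 + c1 * g1
        out[:, n] = upper
    return out


def tofts_forward(ktrans_per_min, ve, vp, aif: AIF,
                  times_s: Optional[np.ndarray] = None) -> np.ndarray:
    """Tissue concentration from the extended Tofts model.

    Parameters broadcast over voxels: scalars give a (T,) curve, (V,) arrays
    give (V, T). k^trans is per minute; the time grid is in seconds.
    """
    times = aif.times_s if times_s is None else np.asarray(times_s, dtype=float)
    cp = aif.on_grid(times)
    kt = np.atleast_1d(np.asarray(ktrans_per_min, dtype=float))
    ve_a = np.atleast_1d(np.asarray(ve, dtype=float))
    vp_a = np.atleast_1d(np.asarray(vp, dtype=float))
    kt, ve_a, vp_a = np.broadcast_arrays(kt, ve_a, vp_a)
    if np.any((ve_a <= 0) & (kt > 0)):
        raise ValidationError("v_e = 0 with k^trans > 0: exchange rate undefined")
    kt_s = kt / 60.0
    with np.errstate(divide="ignore", invalid="ignore"):
        kep_s = np.where(ve_a > 0, kt_s / np.where(ve_a > 0, ve_a, 1.0), 0.0)
    ct = vp_a[:, None] * cp[None, :]
    active = kt_s > 0
    if np.any(active):
        conv = _exp_conv(cp, times, kep_s[active])
        ct[active] += kt_s[active, None] * conv
    if np.isscalar(ktrans_per_min) and np.isscalar(ve) and np.isscalar(vp):
        return ct[0]
    return ct


# ---------------------------------------------------------------------------
# extended Tofts inverse
# ---------------------------------------------------------------------------

def _grid_search(curves: np.ndarray, cp: np.ndarray, times_s: np.ndarray,
                 kep_grid_per_min: np.ndarray) -> tuple[np.ndarray, ...]:
    """For each trial kep, the model is linear in (v_p, k^trans); solve the
    2x2 normal equations for all voxels at once and keep the best kep."""
    n_vox = curves.shape[0]
    best_res = np.full(n_vox, np.inf)
    best = np.zeros((3, n_vox))  # ktrans/min, kep/min, vp
    for kep in kep_grid_per_min:
        g = _exp_conv(cp, times_s, np.array([kep / 60.0]))[0]  # (T,)
        # design [cp, g]; coefficients [vp, ktrans_per_s]
        a11 = cp @ cp
        a12 = cp @ g
        a22 = g @ g
        b1 = curves @ cp
        b2 = curves @ g
        det = a11 * a22 - a12 * a12
        if det <= 1e-30:
            vp = np.where(a11 > 0, b1 / max(a11, 1e-30), 0.0)
            kt_s = np.zeros(n_vox)
        else:
            vp = (a22 * b1 - a12 * b2) / det
            kt_s = (a11 * b2 - a12 * b1) / det
        # enforce nonnegativity by re-solving the clipped 1D problems
        neg_kt = kt_s < 0
        vp = np.where(neg_kt, b1 / max(a11, 1e-30), vp)
        kt_s = np.where(neg_kt, 0.0, kt_s)
        neg_vp = vp < 0
        kt_s = np.where(neg_vp, b2 / max(a22, 1e-30), kt_s)
        vp = np.where(neg_vp, 0.0, vp)
        kt_s = np.clip(kt_s, 0.0, None)
        vp = np.clip(vp, *VP_BOUNDS)
        model = vp[:, None] * cp[None, :] + kt_s[:, None] * g[None, :]
        res = np.sum((curves - model) ** 2, axis=1)
        better = res < best_res
        best_res[better] = res[better]
        best[0, better] = kt_s[better] * 60.0
        best[1, better] = kep
        best[2, better] = vp[better]
    return best[0], best[1], best[2], best_res


def fit_extended_tofts(
    curves: np.ndarray,
    aif: AIF,
    times_s: Optional[np.ndarray] = None,
    kep_grid_per_min: Optional[np.ndarray] = None,
    refine: bool = True,
    max_ktrans_per_min: float = KTRANS_BOUNDS[1],
    zero_tol: float = 1e-12,
) -> PKMaps:
    """Fit (k^trans, v_e, v_p) to one or many concentration curves.

    Multi-start comes from a coarse log-spaced kep grid on which (v_p,
    k^trans) are solved linearly; the best grid point seeds a bounded
    trust-region least-squares refinement. The refined solution is kept only
    when it does not increase the residual, so the final residual is never
    above that of any initialization.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    times = aif.times_s if times_s is None else np.asarray(times_s, dtype=float)
    cp = aif.on_grid(times)
    n_vox = curves.shape[0]
    if kep_grid_per_min is None:
        kep_grid_per_min = np.geomspace(1e-3, 20.0, 40)

    finite = np.all(np.isfinite(curves), axis=1)
    safe = np.where(finite[:, None], curves, 0.0)
    kt0, kep0, vp0, res0 = _grid_search(safe, cp, times, kep_grid_per_min)

    ktrans = np.zeros(n_vox)
    ve = np.zeros(n_vox)
    vp = np.zeros(n_vox)
    residual = np.full(n_vox, np.nan)
    converged = np.zeros(n_vox, dtype=bool)
    valid = finite.copy()

    scale = np.max(np.abs(safe), axis=1)
    degenerate = finite & (scale <= zero_tol)
    ktrans[degenerate] = 0.0
    vp[degenerate] = 0.0
    residual[degenerate] = 0.0
    valid[degenerate] = False  # ve undefined on a zero curve

    for i in np.where(finite & ~degenerate)[0]:
        y = curves[i]
        x0 = np.array([
            np.clip(kt0[i], 1e-4, max_ktrans_per_min),
            np.clip(kt0[i] / max(kep0[i], 1e-6), VE_BOUNDS[0], VE_BOUNDS[1]),
            np.clip(vp0[i], *VP_BOUNDS),
        ])

        def resid(p, y=y):
            return tofts_forward(p[0], p[1], p[2], aif, times) - y

        kt_i, ve_i, vp_i, res_i, conv_i = x0[0], x0[1], x0[2], res0[i], False
        if refine:
            try:
                sol = least_squares(
                    resid, x0,
                    bounds=([0.0, VE_BOUNDS[0], VP_BOUNDS[0]],
                            [max_ktrans_per_min, VE_BOUNDS[1], VP_BOUNDS[1]]),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200)
                if 2.0 * sol.cost <= res_i + 1e-15:
                    kt_i, ve_i, vp_i = sol.x
                    res_i = 2.0 * sol.cost
                    conv_i = sol.success
            except Exception:
                pass
        ktrans[i], ve[i], vp[i] = kt_i, ve_i, vp_i
        residual[i], converged[i] = res_i, conv_i
        if ve_i + vp_i > 1.0 + 1e-6:
            valid[i] = False

    return PKMaps(ktrans_per_min=ktrans, ve=ve, vp=vp, residual=residual,
                  converged=converged, valid=valid)
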