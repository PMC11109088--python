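# Methods

## Signal models and estimators

**Diffusion.** ADC is estimated per replicate from the mono-exponential
decay S(b) = S0·e^(−b·ADC) by log-linear least squares over the acquired
b-values (exactly the two-point formula for the protocol's b = {0, 450}
s/mm²). Voxels with a nonpositive signal at any b are flagged invalid
rather than clamped: the log of a nonpositive signal is undefined and
clamping would bias ADC low. A session ADC is the voxelwise mean over the
replicates valid at that voxel (≥1 valid replicate keeps a voxel). The
protocol b-values are config; deviations raise an error in strict mode and
a warning otherwise, and a series missing the low-b image is a hard error
naming the series, since S0 is then unconstrained.

**T1.** The variable-flip-angle SPGR signal
S(α) = M0 sin α (1−E1)/(1−cos α E1), E1 = e^(−TR/T1), is first linearized
(S/sin α vs. S/tan α) for initial values, then refined by a damped
Gauss–Newton minimization of the nonlinear residual vectorized over all
voxels; step halving guarantees the refinement never increases the residual
relative to its initialization, and the result matches per-voxel
`scipy.optimize.least_squares` to numerical precision (asserted in the
tests). T1 is bounded to [0.05, 10] s — the physiological range at 1.5 T
plus numerical safety — with out-of-bounds solutions clipped and flagged.
Spatial regularization is reduced to optional Gaussian pre-smoothing of the
angle images (default off): a deliberate simplification, adequate for
phantoms, not a reimplementation of any published regularized estimator.
A per-voxel flip-angle scale map can be supplied when an external B1
correction is available; none is computed here.

Inter-image intensity scales (when the angle images were reconstructed
with inconsistent scaling) are estimated by variable projection: the free
log-scales are optimized by nonlinear least squares with the per-voxel
(T1, M0) fit nested inside; at the true factors a consistent series is fit
exactly, so planted factors are recovered to machine precision on noiseless
data.

A precision note: at the protocol TR ≈ 3 ms with tissue T1 ~ 1 s, E1 is
within 0.3% of unity and the angle series carries little T1 contrast, so
per-voxel T1 precision at image SNR 100 is intrinsically ~10% (the exact
NLLS optimum, not an estimator deficiency). The tests therefore assert
optimality and median unbiasedness rather than an arbitrary precision
figure; VOI medians over hundreds of voxels are far tighter.

**DCE.** Dynamic SPGR frames are converted to gadolinium concentration by
normalizing M0 from the mean pre-injection signal and the pre-contrast T1,
inverting the SPGR equation per frame for T1(t), and applying
C(t) = (1/T1(t) − 1/T1(0))/r1. Relaxivity r1 is a required config input
(default 4.5 mM⁻¹s⁻¹ in the phantom protocol, a typical 1.5 T value);
negative concentrations are clipped to zero and flagged, because noise
below baseline is unphysical and destabilizes the convolution fit. Frames
before injection are zero by construction. Injection is detected from the
artery-mean curve (first frame with sustained >5% enhancement over the
running baseline) or taken from an override. The AIF is the pointwise mean
of the top-k artery voxels by peak concentration (k = 10 by default; the
selection criterion is a documented package choice). Blood T1 for the
artery conversion comes from the configured reference value, not the VFA
fit: blood's long T1 makes its high-angle SPGR signals tiny, so a fitted
blood T1 is noise-dominated and was observed to inflate the extracted AIF
several-fold. No hematocrit correction is applied by default; a
1/(1−Hct) factor is available in config.

iAUC is the trapezoidal integral of C(t) over 90 s anchored at injection
time (not per-voxel bolus arrival), with linear interpolation to the
window edge.

**Extended Tofts.** The tissue curve
C_t(t) = v_p C_p(t) + k^trans ∫ C_p e^(−k_ep(t−u)) du, k_ep = k^trans/v_e,
uses an exponential-kernel recursion that is exact for piecewise-linear
C_p — stable at the ~8 s frame spacing. k^trans is expressed per minute
(time grids are in seconds internally, converted explicitly). The inverse
problem is solved per voxel: a coarse log-spaced k_ep grid on which
(v_p, k^trans) are linear and solved in closed form provides the
multi-start; the best grid point seeds a bounded trust-region refinement
whose result is kept only if it does not increase the residual. Bounds:
k^trans ∈ [0, 5] min⁻¹, v_e ∈ (0, 1], v_p ∈ [0, 1]; a zero curve returns
k^trans = v_p = 0 with the voxel flagged degenerate (v_e undefined).

## Response statistics

VOI medians (even counts: mean of the central pair) exclude invalid
voxels; how failed-fit voxels enter VOI summaries is a package decision,
documented here, not an inference about any external analysis. The ADC
repeatability coefficient per tumor is RC = 2.77·√σ², with σ² the
variance (ddof = 1) of replicate VOI medians; tumors without replicates
use the group RC, taken as the median of per-tumor RCs (the choice of
group statistic, and the variance-of-medians estimator itself, are
documented decisions). The Bland–Altman summary pools all within-tumor
replicate pair differences (bias ± 1.96 SD). The non-replicated parameters
use literature bands: T1 ±0.27 s absolute, iAUC ±32% relative, k^trans
−45%/+83% asymmetric-relative, v_e ±0.076 and v_p ±0.0062 absolute — all
config-overridable. A day-1 change is significant outside its band;
a tumor is a pharmacodynamic responder (P) only when the significant
change is in the expected direction (decrease for ADC and T1, increase
otherwise). Since 2.77 = 1.96·√2, a band built from the true within-subject
variance flags 5% of null tumors; with per-tumor variances estimated from
only 3 replicates the χ²₂ estimator noise inflates that rate, which is a
small-sample property of RC estimation, not of the band definition.

Threshold models per parameter search all midpoints of consecutive sorted
distinct baseline values (plus ±∞) for the balanced-accuracy-maximizing
cutpoint, in both inequality directions, keeping the better; ties break
toward the larger minimum margin to the data, then the smaller cutpoint.
McNemar's test on the (predicted, true) discordant pairs uses the exact
binomial below 25 discordants and the continuity-corrected χ² otherwise —
the test's 2×2 construction is a documented package choice. Association
statistics are OLS of day-1 change on baseline (R², F-test p) and Pearson
(optionally Spearman) correlations among parameter changes. Inter-observer
agreement uses the two-way random-effects, absolute-agreement,
single-measures ICC (pingouin's ICC(A,1)); the variant is a documented
choice.

## Pixel-wise predictor

Pixels are labeled p-responders when any parameter's day-1 change exceeds
its band in the response direction; ADC uses the pixel-wise RC
(2.77·√(pooled per-pixel replicate variance) per tumor, or a group value
pooled with equal pixel counts per patient; configured fallback
1.4 × 10⁻³ mm²/s). The classifier is a depth-capped CART decision tree
(scikit-learn; depth 2 by default, since the interesting optima are
depth-1 rules) on the six baseline parameters. Each training draw takes
⌊0.85 × (pixel count of the globally smallest tumor)⌋ pixels from every
patient — "smallest" is interpreted globally across the dataset — with the
two classes globally balanced (|difference| ≤ 1); a patient carrying a
single class contributes only that class and the other patients' splits
shift to restore balance; a class pool smaller than its share is sampled
with replacement. Validation BA is scored per patient on that patient's
held-out pixels, the best-of-repeats model is returned, and
leave-one-patient-out cross-validation retrains on the complement with the
same protocol. Tree depth, split criterion and repeat counts are config
with these documented defaults.

## Digital phantoms

Scenes are small 3D grids (default 32×32×8 at 1.5×1.5×8 mm; 64×64×8 in the
round-trip checks) holding true ADC, T1, M0, k^trans, v_e, v_p maps: a
normal-tissue background, a z-axis artery cylinder painted with v_p = 1
(so it carries the analytic AIF exactly), and non-overlapping ellipsoidal
tumors with per-tumor baseline values drawn uniformly from configured
ranges (ADC 1.0–2.0 × 10⁻³ mm²/s, T1 0.7–1.3 s, k^trans 0.03–0.2 min⁻¹,
v_e 0.1–0.4, v_p 0.01–0.05 — plausible 1.5 T tumor values) plus 3%
voxelwise jitter. The acquisition defaults mirror the study protocol: DWI
at b = {0, 450} s/mm² with 3 replicates; VFA at 15/23/30/60° with TR 3 ms;
48 dynamic frames every 8 s at 30° with injection after 6 frames. The AIF
is a biexponential washout with a bolus-rise factor (peak ≈ 4 mM, tail
≈ 0.2 mM at 5 min).

Treatment effects are applied to the ground-truth parameter maps — not to
signals — so responder truth is unambiguous: the default day-1 model
decreases ADC by 0.15 × 10⁻³ mm²/s and T1 by 2×0.27 s, and increases
k^trans by 2×83%, v_e by 2×0.076 and v_p by 2×0.0062, in a random half of
tumors (per parameter); later visits retain 35% of the effect, i.e. drift
back toward baseline. iAUC has no truth map; its truth is derived from the
noiseless forward model of the tumor-median kinetics. Noise is Rician by
default (magnitude MRI), Gaussian available for analytic checks, with SNR
defined against each series' mean foreground signal (SNR 50 by default —
scanner noise levels are not published for such protocols, so this is a
simulation choice flagged in config). Cohort generation is a pure function
of (config, seed).

What the phantoms do *not* emulate: inter-visit or inter-sequence
mis-registration (scenes are generated pre-aligned; co-registration is out
of scope), B1/flip-angle inhomogeneity, motion, geometric distortion,
partial-volume effects, spatially correlated noise, or intra-tumor
parameter structure beyond uniform jitter. Passing tests therefore
demonstrate the correctness and calibration of the estimators and decision
rules under the stated models — not robustness to the registration and
field-inhomogeneity confounds of real trial data.

## Problem sizes and numerical choices

Defaults keep a full pipeline run (6 patients × 2 visits, all stages) at
about half a minute on one CPU: extended-Tofts fits are restricted to
tumor (and artery) voxels, the k_ep multi-start grid has 40 log-spaced
points, and the VFA Gauss–Newton runs 30 damped iterations. Degenerate
inputs (all-zero voxels, empty masks, single-class label vectors,
windows exceeding the acquisition) raise typed validation errors naming
the offending series or region rather than propagating NaNs; undefined
metric components (zero-denominator sensitivity or specificity) are
reported as NaN with a single-class flag and excluded from BA averaging.
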