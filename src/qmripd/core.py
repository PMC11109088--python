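"""Core containers shared across the pipeline.

Conventions used throughout the package:

* volumes are ``(nx, ny, nz)`` arrays; a series stacks volumes on the last
  axis as ``(nx, ny, nz, n)``;
* time grids are in seconds, TR in milliseconds, T1 in seconds, ADC in
  mm^2/s, k^trans in min^-1, gadolinium concentration in mM;
* invalid voxels are carried in an explicit boolean mask, never silently
  zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: quantitative parameters analyzed by the response stages, in a fixed order
PARAMETERS = ("adc", "t1", "iauc", "ktrans", "ve", "vp")

#: parameters whose pharmacodynamic response direction is a decrease; the
#: rest respond with an increase
DECREASE_PARAMS = frozenset({"adc", "t1"})

#: integer labels of the phantom label map
LABEL_BACKGROUND = 0
LABEL_NORMAL = 1
LABEL_ARTERY = 2
LABEL_TUMOR_START = 10  # tumor i carries label LABEL_TUMOR_START + i


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass
class ImageSeries:
    """A stack of co-registered volumes with per-volume acquisition metadata.

    Exactly the metadata relevant to ``kind`` is populated: ``b_values_s_mm2``
    for diffusion series, ``flip_angles_deg``/``tr_ms`` for variable-flip-angle
    series, ``frame_times_s``/``flip_angle_deg``/``tr_ms`` plus the injection
    frame for dynamic contrast series.
    """

    data: np.ndarray  # (nx, ny, nz, n_volumes)
    kind: str  # 'dwi' | 'vfa' | 'dce'
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b_values_s_mm2: Optional[np.ndarray] = None
    flip_angles_deg: Optional[np.ndarray] = None
    flip_angle_deg: Optional[float] = None
    tr_ms: Optional[float] = None
    frame_times_s: Optional[np.ndarray] = None
    injection_frame: Optional[int] = None
    replicate: int = 0
    series_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError(
                f"series data must be 4D (x, y, z, volume); got shape {self.data.shape}"
            )
        for attr in ("b_values_s_mm2", "flip_angles_deg", "frame_times_s"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float))

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class ParameterMap:
    """Per-voxel values of one quantitative parameter with a validity mask."""

    values: np.ndarray
    units: str
    valid: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValidationError("values and validity mask shapes differ")

    def masked(self) -> np.ndarray:
        """Values with invalid voxels replaced by NaN."""
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out


@dataclass
class AIF:
    """Arterial input function: plasma gadolinium concentration vs. time."""

    times_s: np.ndarray
    cp_mM: np.ndarray
    source: str = "analytic"  # 'measured-from-artery' | 'analytic'
    hematocrit: Optional[float] = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.cp_mM = np.asarray(self.cp_mM, dtype=float)
        if self.times_s.shape != self.cp_mM.shape:
            raise ValidationError("AIF time grid and concentration shapes differ")
        if self.times_s.ndim != 1 or self.times_s.size < 2:
            raise ValidationError("AIF needs a 1D time grid with >= 2 points")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValidationError("AIF time grid must be strictly increasing")
        if np.any(self.cp_mM < -1e-12):
            raise ValidationError("AIF concentrations must be >= 0")

    def on_grid(self, times_s: np.ndarray) -> np.ndarray:
        """Interpolate Cp onto ``times_s``; error if the grid is not covered."""
        times_s = np.asarray(times_s, dtype=float)
        if times_s.min() < self.times_s.min() - 1e-9 or times_s.max() > self.times_s.max() + 1e-9:
            raise ValidationError("requested time grid extends beyond the AIF support")
        return np.interp(times_s, self.times_s, self.cp_mM)


@dataclass
class NoiseModel:
    """Noise family and level for simulated series.

    ``sigma`` is the Gaussian component standard deviation in signal units;
    alternatively ``snr`` defines sigma as S0/snr against a reference signal
    supplied at draw time. Exactly one of the two must be given unless the
    family is ``'none'``.
    """

    family: str = "rician"  # 'rician' | 'gaussian' | 'none'
    sigma: Optional[float] = None
    snr: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in ("rician", "gaussian", "none"):
            raise ValidationError(f"unknown noise family {self.family!r}")
        if self.family != "none":
            if (self.sigma is None) == (self.snr is None):
                raise ValidationError("give exactly one of sigma or snr")
            if self.sigma is not None and self.sigma < 0:
                raise ValidationError("sigma must be >= 0")
            if self.snr is not None and self.snr <= 0:
                raise ValidationError("snr must be > 0")

    def sigma_for(self, reference_signal: float) -> float:
        if self.family == "none":
            return 0.0
        if self.sigma is not None:
            return float(self.sigma)
        return float(reference_signal) / float(self.snr)


def as_rng(rng: "np.random.Generator | int | None") -> np.random.Generator:
    """Normalize a seed / Generator / None into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def spgr_signal(t1_s, m0, flip_angle_deg, tr_ms):
    """Spoiled gradient-echo steady-state signal.

    S = M0 sin(a) (1 - E1) / (1 - cos(a) E1), with E1 = exp(-TR/T1).
    Broadcasts over voxel arrays. T1 in seconds, TR in milliseconds.
    """
    t1_s = np.asarray(t1_s, dtype=float)
    a = np.deg2rad(flip_angle_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.exp(-(tr_ms / 1000.0) / t1_s)
    e1 = np.where(t1_s > 0, e1, 0.0)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)
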