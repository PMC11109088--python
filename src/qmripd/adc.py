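"""Apparent diffusion coefficient mapping from diffusion-weighted series.

ADC comes from the mono-exponential decay S(b) = S0 exp(-b ADC). With two
b-values the fit reduces to the exact two-point formula; with more it is a
log-linear least squares. Voxels with a nonpositive signal at any b cannot
enter the log fit and are flagged invalid rather than clamped — clamping
would bias ADC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import ImageSeries, ParameterMap, ValidationError

__all__ = ["DWIFit", "ProtocolDeviationWarning", "fit_adc", "combine_replicates"]

#: study-protocol diffusion weightings, s/mm^2
PROTOCOL_B_VALUES = (0.0, 450.0)


class ProtocolDeviationWarning(UserWarning):
    """Acquired b-values deviate from the configured protocol."""


@dataclass
class DWIFit:
    """Per-replicate mono-exponential fit."""

    adc: np.ndarray  # mm^2/s
    s0: np.ndarray
    valid: np.ndarray
    replicate: int = 0

    def as_map(self) -> ParameterMap:
        return ParameterMap(values=self.adc, units="mm^2/s", valid=self.valid,
                            name="adc")


def fit_adc(
    series: ImageSeries,
    expected_b: Optional[Sequence[float]] = PROTOCOL_B_VALUES,
    strict: bool = False,
    required_low_b: float = 0.0,
    adc_floor: float = 0.0,
) -> DWIFit:
    """Fit ADC and S0 from a diffusion series with >= 2 distinct b-values.

    A missing low-b (b = ``required_low_b``) image is a hard error naming the
    series, since S0 is then unconstrained. Deviation from ``expected_b``
    raises an error in strict mode and a :class:`ProtocolDeviationWarning`
    otherwise. ADC below ``adc_floor`` is floored and the voxel kept valid
    (noise can push a true nonnegative ADC slightly negative).
    """
    b = series.b_values_s_mm2
    if b is None or b.size < 2 or np.unique(b).size < 2:
        raise ValidationError(
            f"series {series.series_id!r}: need >= 2 distinct b-values")
    if not np.any(np.isclose(b, required_low_b)):
        raise ValidationError(
            f"series {series.series_id!r}: ADC cannot be computed, the "
            f"b = {required_low_b:g} s/mm^2 image was not acquired")
    if expected_b is not None:
        exp = np.sort(np.asarray(expected_b, dtype=float))
        got = np.sort(np.unique(b))
        if got.size != exp.size or not np.allclose(got, exp):
            msg = (f"series {series.series_id!r}: b-values {got.tolist()} deviate "
                   f"from the protocol {exp.tolist()}")
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg, ProtocolDeviationWarning)

    data = series.data
    valid = np.all(data > 0, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(np.where(data > 0, data, 1.0))
    # log-linear LSQ: log S = log S0 - b * ADC  (exact for 2 points)
    bm = b - b.mean()
    denom = float(bm @ bm)
    slope = -(logs @ bm) / denom
    intercept = logs.mean(axis=-1) + slope * b.mean()
    adc = np.where(valid, slope, np.nan)
    flo = adc < adc_floor
    adc = np.where(valid & flo, adc_floor, adc)
    s0 = np.where(valid, np.exp(intercept), np.nan)
    return DWIFit(adc=adc, s0=s0, valid=valid & np.isfinite(adc),
                  replicate=series.replicate)


def combine_replicates(fits: Sequence[DWIFit], min_count: int = 1) -> ParameterMap:
    """Session-mean ADC: voxelwise mean over the replicates valid at that
    voxel; a voxel stays valid when at least ``min_count`` replicates are."""
    if len(fits) == 0:
        raise ValidationError("need >= 1 replicate fit")
    shapes = {f.adc.shape for f in fits}
    if len(shapes) != 1:
        raise ValidationError(f"replicate grids differ: {shapes}")
    stack = np.stack([f.adc for f in fits], axis=-1)
    vstack = np.stack([f.valid for f in fits], axis=-1)
    count = vstack.sum(axis=-1)
    with np.errstate(invalid="ignore"):
        total = np.where(vstack, stack, 0.0).sum(axis=-1)
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    valid = count >= max(min_count, 1)
    mean = np.where(valid, mean, np.nan)
    return ParameterMap(values=mean, units="mm^2/s", valid=valid, name="adc")
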