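"""Voxelwise ADC estimation and computed-DWI (cDWI) extrapolation.

With two acquired b-values and a monoexponential signal model
``S(b) = S(0) * exp(-b * ADC)``, the two-point estimator is exact:

    ADC  = ln(S(b_low) / S(b_high)) / (b_high - b_low)
    S(0) = S(b_low) * exp(+b_low * ADC)

A computed-DWI image at any virtual b-value ``b_c`` is then
``S(b_c) = S(0) * exp(-b_c * ADC)``.  High computed b-values suppress
normal tissue (high ADC) while retaining hyperintense tumor signal
(low ADC), maximizing lesion-to-background contrast for segmentation.

Voxels where either measured signal is non-positive have no defined
log-ratio; they are flagged invalid and their cDWI value is set to 0 so
they cannot survive thresholding.  Negative ADC estimates (noise) are
retained, not clamped, and counted in a summary.

ADC is carried in mm²/s everywhere; display in the conventional
``×10⁻³ mm²/s`` is a presentation concern only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wbdwi.volumes_io import DWIStudy


@dataclass
class ADCMap:
    """Voxelwise apparent diffusion coefficient in mm²/s."""

    values: np.ndarray
    validity_mask: np.ndarray
    n_negative: int = 0

    def __post_init__(self) -> None:
        if self.values.shape != self.validity_mask.shape:
            raise ValueError("values and validity_mask shapes differ")
        if not np.all(np.isfinite(self.values[self.validity_mask])):
            raise ValueError("valid voxels must be finite")


@dataclass
class ComputedDWI:
    """Extrapolated DWI signal at a virtual b-value (arbitrary signal units)."""

    values: np.ndarray
    computed_b: float

    def __post_init__(self) -> None:
        if self.computed_b < 0:
            raise ValueError(f"computed_b must be >= 0, got {self.computed_b}")


def compute_adc(study: DWIStudy) -> ADCMap:
    """Two-point log-ratio ADC estimate for a two-b-value study.

    Voxels with ``S(b_low) <= 0`` or ``S(b_high) <= 0`` are marked
    invalid (value NaN).  Negative estimates are retained but counted.
    """
    s_low = np.asarray(study.low_b_volume.intensities, dtype=np.float64)
    s_high = np.asarray(study.high_b_volume.intensities, dtype=np.float64)
    if s_low.shape != s_high.shape:
        raise ValueError(f"mismatched shapes: {s_low.shape} vs {s_high.shape}")
    valid = (s_low > 0) & (s_high > 0)
    values = np.full(s_low.shape, np.nan, dtype=np.float64)
    db = study.b_high - study.b_low
    values[valid] = np.log(s_low[valid] / s_high[valid]) / db
    n_negative = int(np.sum(values[valid] < 0))
    return ADCMap(values=values, validity_mask=valid, n_negative=n_negative)


def compute_s0(study: DWIStudy, adc_map: ADCMap) -> np.ndarray:
    """Extrapolated signal at b = 0; NaN on invalid voxels."""
    s_low = np.asarray(study.low_b_volume.intensities, dtype=np.float64)
    if s_low.shape != adc_map.values.shape:
        raise ValueError("ADC map does not match study grid")
    s0 = np.full(s_low.shape, np.nan, dtype=np.float64)
    v = adc_map.validity_mask
    s0[v] = s_low[v] * np.exp(study.b_low * adc_map.values[v])
    return s0


def compute_cdwi(study: DWIStudy, adc_map: ADCMap, computed_b: float) -> ComputedDWI:
    """Computed-DWI image ``S(0) * exp(-b_c * ADC)``; invalid voxels -> 0."""
    if computed_b < 0:
        raise ValueError(f"computed_b must be >= 0, got {computed_b}")
    s0 = compute_s0(study, adc_map)
    out = np.zeros(s0.shape, dtype=np.float64)
    v = adc_map.validity_mask
    out[v] = s0[v] * np.exp(-computed_b * adc_map.values[v])
    return ComputedDWI(values=out, computed_b=float(computed_b))
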