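"""Apparent diffusion coefficient (ADC) mapping from a two-point DWI acquisition.

With only two diffusion weightings the mono-exponential model
``S(b) = S0 * exp(-b * ADC)`` has the exact log-linear solution

    ADC = ln(S_low / S_high) / (b_high - b_low)

which coincides with the least-squares line through the two points
``(b, ln S)``.  ADC is reported in the conventional brain-imaging scale of
1e-3 mm^2/s, i.e. a free-water voxel at body temperature reads ~3.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DWIPair", "compute_adc"]


@dataclass
class DWIPair:
    """A pair of diffusion-weighted volumes at two b-values.

    Parameters
    ----------
    s_low, s_high:
        Signal volumes at the low and high b-value (same shape).
    b_low, b_high:
        Diffusion weightings in s/mm^2, with ``b_high > b_low >= 0``.
    """

    s_low: np.ndarray
    s_high: np.ndarray
    b_low: float
    b_high: float

    def __post_init__(self) -> None:
        self.s_low = np.asarray(self.s_low, dtype=float)
        self.s_high = np.asarray(self.s_high, dtype=float)
        if self.s_low.shape != self.s_high.shape:
            raise ValueError(
                f"b-value volumes have different shapes: "
                f"{self.s_low.shape} vs {self.s_high.shape}"
            )
        if self.b_low < 0:
            raise ValueError("b-values must be non-negative")
        if self.b_high <= self.b_low:
            raise ValueError(
                f"b_high must exceed b_low, got b_low={self.b_low}, "
                f"b_high={self.b_high}"
            )


def compute_adc(pair: DWIPair, brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Two-point ADC map in units of 1e-3 mm^2/s.

    Voxels with non-positive signal at either b-value (where the log-linear
    model is undefined) are returned as NaN so that downstream feature
    extraction can exclude them.  Negative ADC values arising from noise are
    retained, not clipped: clipping would bias region means upward.

    Parameters
    ----------
    pair:
        The two b-value volumes.
    brain_mask:
        Optional boolean volume; voxels outside it are NaN.
    """
    db = pair.b_high - pair.b_low
    valid = (pair.s_low > 0) & (pair.s_high > 0)
    if brain_mask is not None:
        valid &= brain_mask.astype(bool)
    adc = np.full(pair.s_low.shape, np.nan)
    # physical ADC in mm^2/s, reported on the 1e-3 scale
    adc[valid] = np.log(pair.s_low[valid] / pair.s_high[valid]) / db * 1e3
    return adc
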