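"""Empirical-null false-discovery-rate bound for R-squared thresholding.

The bound is the proportion of null (non-signal) series whose fitted
R-squared crosses the threshold, divided by the proportion of
threshold-crossing series in the region of interest — a conservative
upper bound on the FDR among the discoveries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NullDistribution", "fdr_upper_bound", "threshold_fits"]

R2_THRESHOLD_DEFAULT = 0.3


@dataclass
class NullDistribution:
    r2_values: np.ndarray
    source: str = "synthetic_noise"

    def __post_init__(self) -> None:
        self.r2_values = np.asarray(self.r2_values, dtype=float)
        if self.r2_values.size and (
            self.r2_values.min() < 0 or self.r2_values.max() > 1
        ):
            raise ValueError("null R2 values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.r2_values.size


def fdr_upper_bound(
    null_r2: np.ndarray | NullDistribution,
    roi_r2: np.ndarray,
    threshold: float = R2_THRESHOLD_DEFAULT,
) -> float:
    """P(null R2 > threshold) / P(ROI R2 > threshold); conservative upper bound."""
    if isinstance(null_r2, NullDistribution):
        null_r2 = null_r2.r2_values
    null_r2 = np.asarray(null_r2, dtype=float)
    roi_r2 = np.asarray(roi_r2, dtype=float)
    if null_r2.size == 0 or roi_r2.size == 0:
        raise ValueError("null and ROI distributions must be nonempty")
    p_null = float(np.mean(null_r2 > threshold))
    p_roi = float(np.mean(roi_r2 > threshold))
    if p_roi == 0:
        raise ValueError("FDR undefined: no discoveries")
    return p_null / p_roi


def threshold_fits(r2_values: np.ndarray, r2_threshold: float = R2_THRESHOLD_DEFAULT) -> np.ndarray:
    """Strict-inequality inclusion mask over fit R-squared values."""
    r2_values = np.asarray(r2_values, dtype=float)
    return r2_values > r2_threshold
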