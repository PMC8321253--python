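"""Threshold-based tumor segmentation baseline.

The classical alternative to statistical segmentation: classify as tumor
every ROI element whose value reaches a fixed percentage of the maximum
reconstructed value within the breast interior.  Sweeping the percentage
(95, 90, 85, 80 by default) exposes the sensitivity/specificity
trade-off inherent to fixed thresholds: lowering the cut can only grow
the mask (thresholded masks are nested), so the ratio of tumor detected
(RD) never decreases while artefact rejection (AR) never increases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import _mask_hausdorff, artefact_rejection, dice, ratio_detected
from .roi import RegionMask

__all__ = ["ThresholdSpec", "threshold_segment", "threshold_sweep"]


@dataclass(frozen=True)
class ThresholdSpec:
    """Percentages of the interior maximum to sweep, each in (0, 100]."""

    percentages: tuple[float, ...] = (95.0, 90.0, 85.0, 80.0)

    def __post_init__(self) -> None:
        if not self.percentages:
            raise ValueError("at least one percentage is required")
        if any(not 0 < p <= 100 for p in self.percentages):
            raise ValueError("percentages must lie in (0, 100]")
        object.__setattr__(self, "percentages",
                           tuple(float(p) for p in self.percentages))


def threshold_segment(component_image: np.ndarray, roi: RegionMask,
                      percent: float) -> RegionMask:
    """Mask of ROI elements with value ≥ (percent/100)·(interior maximum).

    The ≥ comparison keeps percent = 100 nonempty (it selects exactly the
    argmax elements).
    """
    if not 0 < percent <= 100:
        raise ValueError("percent must lie in (0, 100]")
    img = np.asarray(component_image, dtype=float)
    inside = roi.as_bool()
    if img.shape != inside.shape:
        raise ValueError("image and ROI shapes must match")
    if not inside.any():
        raise ValueError("ROI is empty")
    cut = (percent / 100.0) * img[inside].max()
    return RegionMask(inside & (img >= cut), roi.pixel_spacing_mm)


def threshold_sweep(component_image: np.ndarray, roi: RegionMask,
                    spec: ThresholdSpec, ref_tumor: RegionMask) -> pd.DataFrame:
    """Tumor metrics (RD, AR, Dice, H_A) per threshold percentage.

    Returns one row per percentage, in the order given, with columns
    ``percent, rd, ar, dice, hausdorff_mm`` (H_A is NaN when the
    thresholded mask is empty, which cannot happen with ≥).
    """
    if not ref_tumor.as_bool().any():
        raise ValueError("reference tumor mask is empty")
    rows = []
    for percent in spec.percentages:
        rec = threshold_segment(component_image, roi, percent)
        rows.append({
            "percent": percent,
            "rd": ratio_detected(ref_tumor, rec),
            "ar": artefact_rejection(ref_tumor, rec),
            "dice": dice(ref_tumor, rec),
            "hausdorff_mm": _mask_hausdorff(
                ref_tumor.as_bool(), rec.as_bool(), roi.pixel_spacing_mm),
        })
    return pd.DataFrame(rows)
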