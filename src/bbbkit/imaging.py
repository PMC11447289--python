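"""Normalized fluorescence quantification.

Two measurements: (1) per-image mean fluorescence intensity over a region
of interest, normalized to the same experiment's nonstimulated controls to
give a treatment fold-change (used e.g. for the endothelial activation
marker ICAM-1); (2) z-axis mean-intensity profiles of confocal stacks,
re-origined so the membrane plane sits at z = 0 μm, used to localize
basement-membrane proteins on either side of the membrane.

No background subtraction is applied by default; an optional constant
offset can be removed and is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["FoldChangeResult", "ZProfile", "roi_mean", "fold_change", "z_profile"]


@dataclass
class FoldChangeResult:
    """Batch-normalized intensity ratios.

    Each image's ROI mean is divided by the average ROI mean of the control
    images from the same experiment batch, so the control-group mean ratio
    is 1 by construction.
    """

    treated_ratios: np.ndarray
    control_ratios: np.ndarray
    mean_treated: float
    control_mean_intensity: float
    background: float = 0.0


@dataclass
class ZProfile:
    """Mean ROI intensity per slice versus z, membrane plane at z = 0 μm."""

    z: np.ndarray
    mean_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")
        if not np.any(np.isclose(self.z, 0.0)):
            raise ValueError("z must include the membrane plane (0 μm)")

    @property
    def peak_z(self) -> float:
        """z of maximum intensity, μm relative to the membrane."""
        return float(self.z[int(np.argmax(self.mean_intensity))])


def roi_mean(image: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Arithmetic mean intensity over the masked pixels.

    ``roi`` is a boolean mask of the image's shape; None means the whole
    image. An empty mask raises.
    """
    image = np.asarray(image, dtype=float)
    if roi is None:
        return float(image.mean())
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError("roi mask must match image shape")
    if not roi.any():
        raise ValueError("roi mask is empty")
    return float(image[roi].mean())


def fold_change(
    treated: Sequence[np.ndarray],
    controls: Sequence[np.ndarray],
    roi: np.ndarray | None = None,
    background: float = 0.0,
) -> FoldChangeResult:
    """Per-image intensity ratios against the batch-control average.

    Controls must come from the same experiment batch as the treated
    images — the normalization is batch-specific by design. Optional
    constant ``background`` is subtracted from every ROI mean before
    forming ratios and recorded in the result.
    """
    if len(controls) == 0:
        raise ValueError("need at least one control image from the batch")
    ctrl_means = np.array([roi_mean(im, roi) for im in controls]) - background
    ctrl_avg = float(ctrl_means.mean())
    if ctrl_avg == 0:
        raise ValueError("control mean intensity is zero")
    trt_means = np.array([roi_mean(im, roi) for im in treated]) - background
    treated_ratios = trt_means / ctrl_avg
    return FoldChangeResult(
        treated_ratios=treated_ratios,
        control_ratios=ctrl_means / ctrl_avg,
        mean_treated=float(treated_ratios.mean()) if len(treated) else float("nan"),
        control_mean_intensity=ctrl_avg,
        background=background,
    )


def z_profile(
    stack: np.ndarray,
    membrane_index: int,
    roi: np.ndarray | None = None,
    z_spacing: float = 0.2,
) -> ZProfile:
    """Per-slice ROI-mean intensity of a (z, y, x) stack, aligned to the
    membrane plane.

    ``membrane_index`` is the slice containing the membrane; the returned
    z axis is (index − membrane_index) · z_spacing μm, so 0 μm is the
    membrane and profiles from different devices can be overlaid.
    Default slice spacing is 0.2 μm.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (z, y, x); call per channel")
    if not 0 <= membrane_index < stack.shape[0]:
        raise ValueError("membrane_index out of range")
    means = np.array([roi_mean(sl, roi) for sl in stack])
    z = (np.arange(stack.shape[0]) - membrane_index) * z_spacing
    return ZProfile(z=z, mean_intensity=means)
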