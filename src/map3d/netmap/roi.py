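"""ROI-mask extraction from widefield image stacks.

Widefield fluorescence imaging with a DMD in the excitation path can
restrict illumination to the neurons themselves: the 2D illumination mask
is computed from the maximum z-projection of a widefield stack by quantile
thresholding, connected-component labeling, and per-component dilation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

__all__ = ["RoiMasks", "roi_masks_from_stack"]


@dataclass
class RoiMasks:
    mask: np.ndarray  # 2D bool union mask for DMD projection
    labels: np.ndarray  # 2D int connected-component labels (0 = background)
    projection: np.ndarray  # the max z-projection the mask was derived from

    @property
    def n_rois(self) -> int:
        return int(self.labels.max())

    def centroids(self) -> np.ndarray:
        """(n_rois, 2) array of (row, col) component centroids."""
        props = measure.regionprops(self.labels)
        return np.array([p.centroid for p in props])


def roi_masks_from_stack(
    stack: np.ndarray,
    threshold_quantile: float = 0.98,
    dilation_px: int = 2,
) -> RoiMasks:
    """Compute a binary illumination mask and ROI labels from a 3D stack.

    Maximum z-projection → quantile threshold → connected components →
    dilation of each component by ``dilation_px``.  Raising the quantile
    never grows the mask.  An all-zero stack yields an empty mask.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("expected a nonempty (nz, ny, nx) stack")
    if not 0.0 <= threshold_quantile <= 1.0:
        raise ValueError("threshold_quantile must be in [0, 1]")
    proj = stack.max(axis=0)
    thr = np.quantile(proj, threshold_quantile)
    bw = proj > thr
    labels = measure.label(bw, connectivity=2)
    if dilation_px > 0 and labels.max() > 0:
        footprint = morphology.disk(dilation_px)
        # per-component dilation, preserving labels of overlapping growth
        grown = morphology.dilation(labels, footprint)
        labels = np.where(labels > 0, labels, grown)
    mask = labels > 0
    return RoiMasks(mask=mask, labels=labels, projection=proj)
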