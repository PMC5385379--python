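"""Endothelial permeability readout: the Npx50 changed-pixel count.

After an albumin-binding, T1-shortening contrast agent, leaky endothelium
lets the agent accumulate around the vessel, shortening perivascular T1.
Npx50 is the count of pixels around the lumen whose T1 changed by more than
50 % between the pre- and post-contrast T1 maps — an operator-independent
permeability statistic that avoids drawing a precise ROI by hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage

from .t1map import T1Map

__all__ = [
    "perivascular_roi",
    "relative_t1_change",
    "compute_npx50",
    "render_overlay",
    "PermeabilityResult",
]


def _t1_array(t1: Union[np.ndarray, T1Map]) -> np.ndarray:
    if isinstance(t1, T1Map):
        return t1.t1_ms
    return np.asarray(t1, dtype=float)


def perivascular_roi(lumen_mask: np.ndarray, rim_thickness_px: int) -> np.ndarray:
    """Ring-shaped analysis region around the lumen.

    The ROI is the morphological dilation of the lumen by
    ``rim_thickness_px`` (4-connected in-plane) minus the lumen itself, so
    it is always disjoint from the lumen.  For 3D masks the dilation is
    performed slice-wise: slices are thick relative to in-plane pixels, and
    the published analysis rings each cross-section independently.
    """
    if rim_thickness_px < 1:
        raise ValueError("rim_thickness_px must be >= 1")
    lumen = np.asarray(lumen_mask, dtype=bool)
    if not lumen.any():
        raise ValueError("lumen mask is empty")
    if lumen.ndim == 2:
        dilated = ndimage.binary_dilation(
            lumen, structure=ndimage.generate_binary_structure(2, 1),
            iterations=rim_thickness_px,
        )
    elif lumen.ndim == 3:
        structure = np.zeros((1, 3, 3), dtype=bool)
        structure[0] = ndimage.generate_binary_structure(2, 1)
        dilated = ndimage.binary_dilation(
            lumen, structure=structure, iterations=rim_thickness_px
        )
    else:
        raise ValueError("lumen mask must be 2D or 3D")
    return dilated & ~lumen


def relative_t1_change(
    t1_pre: Union[np.ndarray, T1Map],
    t1_post: Union[np.ndarray, T1Map],
    direction: str = "decrease",
) -> np.ndarray:
    """Per-pixel relative T1 change between co-registered maps.

    ``direction='decrease'`` returns (pre - post) / pre, positive where the
    contrast agent shortened T1; ``'absolute'`` returns |pre - post| / pre.
    Pixels undefined (NaN) in either map, or with non-positive pre T1, are
    NaN in the output.
    """
    pre = _t1_array(t1_pre)
    post = _t1_array(t1_post)
    if pre.shape != post.shape:
        raise ValueError(f"shape mismatch: pre {pre.shape} vs post {post.shape}")
    if direction not in ("decrease", "absolute"):
        raise ValueError(f"unknown direction {direction!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        change = (pre - post) / pre
    if direction == "absolute":
        change = np.abs(change)
    change = np.where(np.isfinite(pre) & np.isfinite(post) & (pre > 0), change, np.nan)
    return change


@dataclass
class PermeabilityResult:
    """Npx50 statistic together with the masks needed for overlay rendering.

    ``roi_mask`` holds the evaluable ROI pixels (undefined-fit pixels already
    excluded, their count in ``n_excluded``); ``changed_mask`` marks the
    pixels counted in ``npx50``.
    """

    npx50: int
    changed_mask: np.ndarray
    roi_mask: np.ndarray
    threshold: float
    direction: str
    n_excluded: int

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if np.any(self.changed_mask & ~self.roi_mask):
            raise ValueError("changed_mask must be a subset of roi_mask")
        if not (0 <= self.npx50 <= int(self.roi_mask.sum())):
            raise ValueError("npx50 must lie within the ROI size")

    @property
    def roi_size(self) -> int:
        return int(self.roi_mask.sum())


def compute_npx50(
    t1_pre: Union[np.ndarray, T1Map],
    t1_post: Union[np.ndarray, T1Map],
    roi_mask: np.ndarray,
    threshold: float = 0.50,
    direction: str = "decrease",
) -> PermeabilityResult:
    """Count ROI pixels whose T1 changed by strictly more than ``threshold``.

    A pixel at exactly the threshold is not counted (strict inequality).
    Pixels undefined in either T1 map are removed from the ROI before
    counting; if none remain the statistic is undefined and an error is
    raised.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    roi = np.asarray(roi_mask, dtype=bool)
    pre = _t1_array(t1_pre)
    if roi.shape != pre.shape:
        raise ValueError(f"ROI shape {roi.shape} does not match maps {pre.shape}")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    change = relative_t1_change(t1_pre, t1_post, direction)
    evaluable = roi & np.isfinite(change)
    n_excluded = int(roi.sum() - evaluable.sum())
    if not evaluable.any():
        raise ValueError("no evaluable pixels: entire ROI undefined in a T1 map")
    changed = evaluable & (change > threshold)
    return PermeabilityResult(
        npx50=int(changed.sum()),
        changed_mask=changed,
        roi_mask=evaluable,
        threshold=float(threshold),
        direction=direction,
        n_excluded=n_excluded,
    )


def render_overlay(
    result: PermeabilityResult,
    background: np.ndarray,
    path,
    slice_index: Optional[int] = None,
):
    """Save a cross-section PNG with the changed (Npx50) pixels marked red.

    ``background`` is a 2D/3D anatomical or T1 image of the same shape as the
    result's masks; for 3D inputs ``slice_index`` selects the rendered slice
    (default: the slice with the most changed pixels).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bg = np.asarray(background, dtype=float)
    changed = result.changed_mask
    if bg.ndim == 3:
        if slice_index is None:
            slice_index = int(np.argmax(changed.reshape(changed.shape[0], -1).sum(1)))
        bg = bg[slice_index]
        changed = changed[slice_index]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(bg, cmap="gray", interpolation="nearest")
    overlay = np.zeros(bg.shape + (4,))
    overlay[changed] = (1.0, 0.0, 0.0, 1.0)
    ax.imshow(overlay, interpolation="nearest")
    ax.set_axis_off()
    ax.set_title(f"Npx50 = {result.npx50}")
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return path
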