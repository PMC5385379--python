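"""Vasomotor-response quantification from gated cine angiograms.

The endothelial-function readout is the percent change of the end-diastolic
lumen volume of the brachiocephalic artery (BCA) between scans acquired
before and after acetylcholine: negative = vasoconstriction (dysfunctional
endothelium), positive = vasodilatation.  The analysis mirrors the published
procedure: pick the diastolic cardiac frame (minimal lumen area), take five
contiguous slices ending just before the vessel's branch, segment each
cross-section by intensity thresholding, and stack the areas into a volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .phantom import CineVolume

__all__ = [
    "SliceSegmentation",
    "LumenSegmentation",
    "VasomotionResult",
    "segment_lumen_slice",
    "select_diastolic_frame",
    "select_analysis_slices",
    "reconstruct_volume",
    "volume_change_percent",
    "measure_vasomotion",
]


@dataclass
class SliceSegmentation:
    """One slice's lumen mask with its physical cross-sectional area."""

    mask: np.ndarray
    area_mm2: float
    threshold: float


@dataclass
class LumenSegmentation:
    """Per-slice lumen masks and areas over a contiguous slice range."""

    masks: list
    areas_mm2: np.ndarray
    thresholds: np.ndarray
    slice_indices: Tuple[int, ...]


@dataclass
class VasomotionResult:
    """End-diastolic BCA volumes before/after acetylcholine and % change."""

    v_pre_mm3: float
    v_post_mm3: float
    percent_change: float
    diastolic_frame_pre: int
    diastolic_frame_post: int
    slice_range: Tuple[int, ...]
    segmentation_pre: LumenSegmentation
    segmentation_post: LumenSegmentation

    def __post_init__(self) -> None:
        if self.v_pre_mm3 <= 0 or self.v_post_mm3 <= 0:
            raise ValueError("volumes must be positive")
        if not np.isfinite(self.percent_change):
            raise ValueError("percent_change must be finite")


def _lumen_threshold(
    image: np.ndarray,
    method: str,
    seed_point: Optional[Tuple[int, int]],
    fraction: float,
) -> float:
    """Threshold between the background mode and the lumen peak.

    The default rule places the cut a ``fraction`` (default half) of the way
    from the background level (image median — background dominates the FOV)
    to the lumen peak (a high percentile, robust to isolated noise spikes).
    Otsu's method is available as an alternative.
    """
    if method == "otsu":
        return float(filters.threshold_otsu(image))
    if method != "fraction-of-max":
        raise ValueError(f"unknown segmentation method {method!r}")
    background = float(np.median(image))
    peak = float(np.percentile(image, 99.9))
    return background + fraction * (peak - background)


def segment_lumen_slice(
    image_2d: np.ndarray,
    pixel_area_mm2: float,
    method: str = "fraction-of-max",
    seed_point: Optional[Tuple[int, int]] = None,
    fraction: float = 0.5,
) -> SliceSegmentation:
    """Threshold one cross-section and keep the lumen containing the seed.

    The slice is thresholded, the connected component containing (or
    nearest to) ``seed_point`` is retained, holes are filled, and the area
    is the pixel count times the in-plane pixel area.
    """
    img = np.asarray(image_2d, dtype=float)
    if img.ndim != 2:
        raise ValueError("image_2d must be two-dimensional")
    if np.ptp(img) == 0:
        raise ValueError("cannot segment a constant image")
    if pixel_area_mm2 <= 0:
        raise ValueError("pixel_area_mm2 must be positive")
    thr = _lumen_threshold(img, method, seed_point, fraction)
    binary = img > thr
    if not binary.any():
        raise ValueError(
            f"empty mask at threshold {thr:.3g} "
            f"(image range {img.min():.3g}..{img.max():.3g})"
        )
    labelled = measure.label(binary, connectivity=1)
    if seed_point is None:
        # keep the largest component
        counts = np.bincount(labelled.ravel())
        counts[0] = 0
        keep = int(np.argmax(counts))
    else:
        r, c = seed_point
        if 0 <= r < img.shape[0] and 0 <= c < img.shape[1] and labelled[r, c]:
            keep = int(labelled[r, c])
        else:
            fg = np.argwhere(binary)
            d2 = (fg[:, 0] - r) ** 2 + (fg[:, 1] - c) ** 2
            nearest = fg[int(np.argmin(d2))]
            keep = int(labelled[nearest[0], nearest[1]])
    mask = ndimage.binary_fill_holes(labelled == keep)
    area = float(mask.sum()) * float(pixel_area_mm2)
    return SliceSegmentation(mask=mask, area_mm2=area, threshold=float(thr))


def _pixel_area(cine: CineVolume) -> float:
    return cine.voxel_mm[0] * cine.voxel_mm[1]


def select_diastolic_frame(
    cine: CineVolume,
    seed_point: Tuple[int, int],
    slices: Optional[Sequence[int]] = None,
    method: str = "fraction-of-max",
    fraction: float = 0.5,
) -> int:
    """Frame index of minimal total segmented lumen area (end diastole).

    Areas are summed over ``slices`` (all slices by default); ties break to
    the lowest frame index.  A single-frame cine returns 0.
    """
    if cine.n_frames == 1:
        return 0
    if slices is None:
        slices = range(cine.intensities.shape[0])
    px_area = _pixel_area(cine)
    totals = np.full(cine.n_frames, np.inf)
    any_success = False
    for f in range(cine.n_frames):
        vol = cine.frame(f)
        total = 0.0
        ok = False
        for k in slices:
            try:
                seg = segment_lumen_slice(vol[k], px_area, method, seed_point, fraction)
            except ValueError:
                continue
            total += seg.area_mm2
            ok = True
        if ok:
            totals[f] = total
            any_success = True
    if not any_success:
        raise ValueError("lumen segmentation failed on every frame")
    return int(np.argmin(totals))


def select_analysis_slices(
    cine: CineVolume,
    frame: int,
    seed_point: Optional[Tuple[int, int]] = None,
    length: int = 5,
    override: Optional[Sequence[int]] = None,
    method: str = "fraction-of-max",
    fraction: float = 0.5,
    min_component_px: int = 5,
) -> Tuple[int, ...]:
    """Contiguous analysis slices ending just before the vessel branch.

    The branch is detected as the first slice whose thresholded lumen mask
    splits into two connected components (of at least ``min_component_px``
    pixels); the returned range is the ``length`` slices immediately
    proximal to it.  An explicit ``override`` range is returned verbatim.
    """
    n_slices = cine.intensities.shape[0]
    if override is not None:
        sl = tuple(int(s) for s in override)
        if len(sl) > n_slices:
            raise ValueError("override longer than available slices")
        return sl
    if length > n_slices:
        raise ValueError("requested length exceeds available slices")
    vol = cine.frame(frame)
    branch = None
    for k in range(n_slices):
        img = vol[k]
        if np.ptp(img) == 0:
            continue
        thr = _lumen_threshold(img, method, seed_point, fraction)
        labelled = measure.label(img > thr, connectivity=1)
        counts = np.bincount(labelled.ravel())
        if (counts[1:] >= min_component_px).sum() >= 2:
            branch = k
            break
    if branch is None:
        raise ValueError("no branch found: lumen never splits into two components")
    if branch < length:
        raise ValueError(
            f"branch at slice {branch}: fewer than {length} proximal slices available"
        )
    return tuple(range(branch - length, branch))


def reconstruct_volume(
    seg: Iterable[float] | LumenSegmentation, slice_thickness_mm: float
) -> float:
    """Lumen volume (mm^3) by the rectangular rule over per-slice areas."""
    areas = seg.areas_mm2 if isinstance(seg, LumenSegmentation) else np.asarray(
        list(seg), dtype=float
    )
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("no slices: cannot reconstruct a volume")
    if slice_thickness_mm <= 0:
        raise ValueError("slice_thickness_mm must be positive")
    return float(np.sum(areas) * slice_thickness_mm)


def volume_change_percent(v_pre: float, v_post: float) -> float:
    """Percent change of end-diastolic volume: 100 x (post - pre) / pre."""
    if v_pre <= 0:
        raise ValueError("v_pre must be positive")
    return 100.0 * (v_post - v_pre) / v_pre


def _segment_range(
    cine: CineVolume,
    frame: int,
    slices: Sequence[int],
    seed_point: Tuple[int, int],
    method: str,
    fraction: float,
) -> LumenSegmentation:
    px_area = _pixel_area(cine)
    vol = cine.frame(frame)
    segs = [
        segment_lumen_slice(vol[k], px_area, method, seed_point, fraction)
        for k in slices
    ]
    return LumenSegmentation(
        masks=[s.mask for s in segs],
        areas_mm2=np.array([s.area_mm2 for s in segs]),
        thresholds=np.array([s.threshold for s in segs]),
        slice_indices=tuple(slices),
    )


def measure_vasomotion(
    cine_pre: CineVolume,
    cine_post: CineVolume,
    seed_point: Tuple[int, int],
    slices: Optional[Sequence[int]] = None,
    method: str = "fraction-of-max",
    fraction: float = 0.5,
) -> VasomotionResult:
    """Full vasomotor analysis of a pre/post-acetylcholine cine pair.

    The diastolic frame is selected per scan; the analysis slice range is
    determined once on the pre-acetylcholine scan (the scans are
    co-registered by acquisition) and reused for the post scan.
    """
    f_pre = select_diastolic_frame(cine_pre, seed_point, method=method, fraction=fraction)
    f_post = select_diastolic_frame(cine_post, seed_point, method=method, fraction=fraction)
    if slices is None:
        slices = select_analysis_slices(
            cine_pre, f_pre, seed_point, method=method, fraction=fraction
        )
    seg_pre = _segment_range(cine_pre, f_pre, slices, seed_point, method, fraction)
    seg_post = _segment_range(cine_post, f_post, slices, seed_point, method, fraction)
    dz = cine_pre.protocol.slice_thickness_mm
    v_pre = reconstruct_volume(seg_pre, dz)
    v_post = reconstruct_volume(seg_post, dz)
    return VasomotionResult(
        v_pre_mm3=v_pre,
        v_post_mm3=v_post,
        percent_change=volume_change_percent(v_pre, v_post),
        diastolic_frame_pre=f_pre,
        diastolic_frame_post=f_post,
        slice_range=tuple(slices),
        segmentation_pre=seg_pre,
        segmentation_post=seg_post,
    )
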