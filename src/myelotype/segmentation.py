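"""GM-referenced T1-hypointensity segmentation and a FLAIR fallback.

T1 lesions are segmented by intensity threshold referenced to cortical grey
matter: threshold = mean(GM T1) - k * SD(GM T1), with scaling factor k
(optimized elsewhere on a ROC grid; the published optimum is k = 1.7).
Voxels strictly below the threshold inside a search region (by default the
T2 lesion mask intersected with white matter) are kept, and connected
components smaller than a voxel minimum are discarded (26-connectivity).

SD uses the population convention (divisor n); the choice is recorded on
the returned stats.  GM statistics are computed after eroding the GM mask
(default 1 voxel) to suppress partial-volume voxels at the CSF and WM
boundaries.

``segment_t2_fallback`` is a simple intensity rule for T2-hyperintensity
masks on synthetic phantoms; real pipelines supply their own T2 masks.
It thresholds FLAIR above a robust WM reference (median + z * 1.4826*MAD),
which stays calibrated when a sizable fraction of WM is lesional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, ScalarVolume, check_same_geometry

__all__ = [
    "GMIntensityStats",
    "ThresholdSpec",
    "gm_intensity_stats",
    "t1_threshold",
    "segment_t1_lesions",
    "segment_t2_fallback",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class GMIntensityStats:
    """Mean/SD of cortical GM T1 intensity over the (eroded) GM mask."""

    mean: float
    sd: float
    n_voxels: int
    sd_convention: str = "population"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n_voxels <= 0:
            raise ValueError("stats require at least one voxel")


@dataclass(frozen=True)
class ThresholdSpec:
    """A realized threshold: value = GM mean - k * GM SD."""

    k: float
    threshold_value: float
    search_region: str = "within_t2_mask"  # or "whole_wm"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("scaling factor k must be positive")
        if self.search_region not in ("within_t2_mask", "whole_wm"):
            raise ValueError(f"unknown search_region {self.search_region!r}")


def gm_intensity_stats(t1: ScalarVolume, gm_mask: BinaryMask,
                       erode_voxels: int = 1) -> GMIntensityStats:
    """Mean and population SD of T1 intensity over the eroded GM mask."""
    check_same_geometry(t1, gm_mask, what="t1/gm_mask")
    m = gm_mask.data
    if erode_voxels < 0:
        raise ValueError("erode_voxels must be non-negative")
    if erode_voxels:
        m = ndimage.binary_erosion(m, iterations=erode_voxels)
    n = int(m.sum())
    if n == 0:
        raise ValueError(
            f"GM mask empty after eroding {erode_voxels} voxel(s); reduce erosion"
        )
    vals = t1.data[m]
    return GMIntensityStats(mean=float(vals.mean()), sd=float(vals.std(ddof=0)),
                            n_voxels=n)


def t1_threshold(stats: GMIntensityStats, k: float,
                 search_region: str = "within_t2_mask") -> ThresholdSpec:
    """Threshold value = GM mean - k * GM SD (strictly decreasing in k)."""
    if k <= 0:
        raise ValueError("scaling factor k must be positive")
    return ThresholdSpec(k=float(k), threshold_value=stats.mean - k * stats.sd,
                         search_region=search_region)


def _filter_small_components(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labels]


def segment_t1_lesions(t1: ScalarVolume, spec: ThresholdSpec,
                       t2_mask: BinaryMask, wm_mask: BinaryMask,
                       min_component_voxels: int = 3) -> BinaryMask:
    """Threshold T1 below ``spec.threshold_value`` inside the search region.

    The search region is ``t2_mask & wm_mask`` (default) or all of WM; the
    comparison is strict (<).  Components under ``min_component_voxels``
    (26-connectivity) are removed.  The result is always a subset of the
    search region, and masks are nested across k: larger k, smaller mask.
    """
    check_same_geometry(t1, t2_mask, wm_mask, what="t1/t2_mask/wm_mask")
    if spec.search_region == "within_t2_mask":
        region = t2_mask.data & wm_mask.data
    else:
        region = wm_mask.data
    raw = region & (t1.data < spec.threshold_value)
    out = _filter_small_components(raw, min_component_voxels)
    return BinaryMask(out, t1.voxel_mm, t1.space)


def segment_t2_fallback(flair: ScalarVolume, wm_mask: BinaryMask,
                        z_cut: float = 3.0,
                        min_component_voxels: int = 3) -> BinaryMask:
    """Hyperintensity mask: FLAIR above a robust WM reference.

    Threshold = median(WM FLAIR) + z_cut * 1.4826 * MAD(WM FLAIR).  The
    robust location/scale keep the threshold anchored to normal-appearing
    WM even when lesions occupy a large share of the mask.  Intended for
    synthetic phantoms; established pipelines provide T2 masks upstream.
    """
    check_same_geometry(flair, wm_mask, what="flair/wm_mask")
    if not wm_mask.data.any():
        raise ValueError("WM mask is empty")
    vals = flair.data[wm_mask.data]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    thr = med + z_cut * 1.4826 * mad
    raw = wm_mask.data & (flair.data > thr)
    out = _filter_small_components(raw, min_component_voxels)
    return BinaryMask(out, flair.voxel_mm, flair.space)
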