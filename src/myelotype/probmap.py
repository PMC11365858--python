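"""Voxel-wise lesion probability maps over co-aligned subjects.

Each subject contributes a binary lesion mask in a shared space (alignment
is a precondition; nonlinear registration is upstream infrastructure, not
part of this package).  The probability map is the per-voxel fraction of
subjects with a lesion, optionally blurred by a Gaussian in physical units
to absorb residual spatial mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, GeometryError

__all__ = ["ProbabilityMap", "probability_map", "gaussian_smooth"]


@dataclass
class ProbabilityMap:
    data: np.ndarray
    voxel_mm: tuple[float, float, float]
    n_subjects: int
    smoothing_sigma_mm: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probability values must lie in [0, 1]")

    @property
    def shape(self):
        return self.data.shape


def probability_map(masks: list[BinaryMask]) -> ProbabilityMap:
    """Per-voxel fraction of subjects whose mask is set.

    All masks must share shape and voxel size; a mismatch names the
    offending subject index.  With no smoothing the values are multiples
    of 1/n.
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    ref = masks[0]
    acc = np.zeros(ref.shape, dtype=np.float64)
    for i, m in enumerate(masks):
        if m.shape != ref.shape or not np.allclose(m.voxel_mm, ref.voxel_mm):
            raise GeometryError(f"mask for subject index {i} does not match "
                                f"the reference geometry")
        acc += m.data
    acc /= len(masks)
    return ProbabilityMap(acc, ref.voxel_mm, n_subjects=len(masks))


def gaussian_smooth(pmap: ProbabilityMap, sigma_mm: float) -> ProbabilityMap:
    """Gaussian blur with sigma in mm (divided per-axis by voxel size).

    Reflective boundaries; output clipped to [0, 1]; sigma 0 is the
    identity.
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_mm == 0:
        return ProbabilityMap(pmap.data.copy(), pmap.voxel_mm, pmap.n_subjects,
                              smoothing_sigma_mm=0.0)
    sigma_vox = [sigma_mm / v for v in pmap.voxel_mm]
    sm = ndimage.gaussian_filter(pmap.data, sigma=sigma_vox, mode="reflect")
    return ProbabilityMap(np.clip(sm, 0.0, 1.0), pmap.voxel_mm, pmap.n_subjects,
                          smoothing_sigma_mm=float(sigma_mm))
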