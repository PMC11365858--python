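"""Millilitre volumetry of lesion masks and the T1/T2% ratio.

The classifier consumes two scalars per subject: the T1-hypointensity volume
in ml and the percentage of the T2-hyperintensity volume occupied by T1
hypointensities (T1/T2%).  ml is identified with cm^3 (1000 mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass

from .grids import BinaryMask

__all__ = ["LesionMetrics", "mask_volume_ml", "t1_t2_ratio_pct", "UndefinedRatioError"]

MM3_PER_ML = 1000.0


class UndefinedRatioError(ZeroDivisionError):
    """T1/T2% is undefined when the T2 volume is zero.

    Subjects without measurable T2 load must be routed to low-T2 handling
    before the ratio is requested.
    """


@dataclass(frozen=True)
class LesionMetrics:
    """Per-subject lesion volumetry: T2 ml, T1 ml, and T1/T2 x 100."""

    t2_ml: float
    t1_ml: float
    ratio_pct: float

    def __post_init__(self) -> None:
        if self.t2_ml < 0 or self.t1_ml < 0:
            raise ValueError("lesion volumes must be non-negative")


def mask_volume_ml(mask: BinaryMask) -> float:
    """Volume of the true voxels in millilitres.

    count(true voxels) x voxel volume (mm^3) / 1000.  Anisotropic voxels are
    handled through the mask's stored voxel dimensions.
    """
    return mask.n_voxels * mask.voxel_volume_mm3 / MM3_PER_ML


def t1_t2_ratio_pct(t1_ml: float, t2_ml: float) -> float:
    """Percentage of T2 lesion volume occupied by T1 lesions: 100 * t1 / t2.

    Raises
    ------
    UndefinedRatioError
        If ``t2_ml`` is zero (or negative input is supplied).
    """
    if t1_ml < 0 or t2_ml < 0:
        raise ValueError("lesion volumes must be non-negative")
    if t2_ml == 0:
        raise UndefinedRatioError("T1/T2% undefined for zero T2 volume")
    return 100.0 * t1_ml / t2_ml


def lesion_metrics(t1_ml: float, t2_ml: float) -> LesionMetrics:
    """Bundle volumes with their ratio (requires ``t2_ml > 0``)."""
    return LesionMetrics(t2_ml=t2_ml, t1_ml=t1_ml, ratio_pct=t1_t2_ratio_pct(t1_ml, t2_ml))
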