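"""Zero-intercept linear calibration between T1-weighted acquisitions.

T1-hypointensity volumes measured on a FLASH acquisition systematically
underestimate those measured on MPRAGE; the two are related by a straight
line through the origin.  The published conversion is

    volume_MPRAGE = 1.5327 x volume_FLASH

fitted on brains scanned with both protocols.  ``fit_zero_intercept``
re-derives such a slope by least squares through the origin
(slope = sum(x*y) / sum(x^2)); an optional free-intercept diagnostic fit is
available but never used in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PUBLISHED_FLASH_TO_MPRAGE_SLOPE",
    "CalibrationModel",
    "fit_zero_intercept",
    "apply_calibration",
    "fit_free_intercept",
]

#: Published FLASH -> MPRAGE T1-hypointensity volume conversion factor.
PUBLISHED_FLASH_TO_MPRAGE_SLOPE = 1.5327


@dataclass(frozen=True)
class CalibrationModel:
    slope: float
    n_pairs: int
    residual_rmse: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


def fit_zero_intercept(x_flash, y_mprage) -> CalibrationModel:
    """Least-squares line through the origin: slope = sum(xy)/sum(x^2).

    Raises
    ------
    ValueError
        Fewer than 2 pairs, mismatched lengths, or all x equal to zero.
    """
    x = np.asarray(x_flash, dtype=float)
    y = np.asarray(y_mprage, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 calibration pairs")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("cannot fit through origin: all x are zero")
    slope = float(np.dot(x, y)) / sxx
    rmse = float(np.sqrt(np.mean((y - slope * x) ** 2)))
    return CalibrationModel(slope=slope, n_pairs=int(x.size), residual_rmse=rmse)


def apply_calibration(model: CalibrationModel, flash_ml: float) -> float:
    """Convert a FLASH-derived volume (ml) to the MPRAGE scale."""
    if flash_ml < 0:
        raise ValueError("volumes must be non-negative")
    return model.slope * flash_ml


def published_model() -> CalibrationModel:
    """The published conversion as a ready-to-apply model."""
    return CalibrationModel(slope=PUBLISHED_FLASH_TO_MPRAGE_SLOPE, n_pairs=35,
                            residual_rmse=float("nan"))


def fit_free_intercept(x_flash, y_mprage) -> tuple[float, float]:
    """Diagnostic ordinary least squares fit (slope, intercept).

    Provided to check how far the data are from the zero-intercept
    assumption; the pipeline itself always uses the origin-constrained fit.
    """
    x = np.asarray(x_flash, dtype=float)
    y = np.asarray(y_mprage, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
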