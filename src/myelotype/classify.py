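"""Three-way MS subtype decision rule and its validation metrics.

A subject with total T2-hyperintensity volume above 2 ml is called MCMS
(myelocortical MS) when both T1-hypointensity metrics are small --
T1 volume < 0.75 ml AND T1/T2% < 1.9% -- and TMS (typical MS) otherwise.
Subjects at or below 2 ml of T2 load cannot be distinguished by the rule:
in an in-vivo cohort they are reported as a third LOW_T2 class, in the
postmortem validation setting they are excluded up front (together with
donors aged 65 or older).

All printed inequalities are treated as strict; a subject with t2_ml
exactly 2.0 falls in LOW_T2 / fails eligibility.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClassLabel",
    "ClassifierThresholds",
    "ConfusionMatrix",
    "classify_subject",
    "eligibility",
    "confusion_metrics",
    "stratify_cohort",
    "StratificationResult",
]


class ClassLabel(str, enum.Enum):
    TMS = "TMS"
    MCMS = "MCMS"
    LOW_T2 = "LOW_T2"
    INELIGIBLE = "INELIGIBLE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds; defaults are the published operating points."""

    t2_min_ml: float = 2.0
    t1_max_ml: float = 0.75
    ratio_max_pct: float = 1.9
    age_max_years: float = 65.0

    def __post_init__(self) -> None:
        if min(self.t2_min_ml, self.t1_max_ml, self.ratio_max_pct, self.age_max_years) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with MCMS as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def classify_subject(t2_ml: float, t1_ml: float,
                     thresholds: ClassifierThresholds = ClassifierThresholds()) -> ClassLabel:
    """Apply the three-way rule to one subject's lesion volumes.

    LOW_T2 if t2_ml <= 2 ml; else MCMS if t1_ml < 0.75 ml and
    100*t1/t2 < 1.9%; else TMS.  The ratio is computed internally, so only
    the two volumes are required.
    """
    if t2_ml < 0 or t1_ml < 0:
        raise ValueError("lesion volumes must be non-negative")
    if not t2_ml > thresholds.t2_min_ml:
        return ClassLabel.LOW_T2
    ratio_pct = 100.0 * t1_ml / t2_ml
    if t1_ml < thresholds.t1_max_ml and ratio_pct < thresholds.ratio_max_pct:
        return ClassLabel.MCMS
    return ClassLabel.TMS


def eligibility(t2_ml: float, age_years: float,
                thresholds: ClassifierThresholds = ClassifierThresholds()) -> bool:
    """Postmortem-validation inclusion: T2 volume > 2 ml and age < 65 years."""
    if t2_ml < 0 or age_years < 0:
        raise ValueError("inputs must be non-negative")
    return t2_ml > thresholds.t2_min_ml and age_years < thresholds.age_max_years


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from a 2x2 matrix.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    accuracy = (tp+tn)/total.  Both class margins must be non-empty.
    """
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("confusion matrix has an empty class margin")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    return sens, spec, acc


@dataclass
class StratificationResult:
    """Labelled cohort with group counts/percentages and optional validation."""

    records: pd.DataFrame
    counts: dict[str, int]
    percentages: dict[str, int]
    confusion: ConfusionMatrix | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None


_REQUIRED = ("t2_ml", "t1_ml")


def stratify_cohort(records: pd.DataFrame,
                    thresholds: ClassifierThresholds = ClassifierThresholds(),
                    mode: str = "in_vivo") -> StratificationResult:
    """Label every record and summarize the partition.

    Parameters
    ----------
    records
        One row per subject with at least ``t2_ml`` and ``t1_ml`` columns;
        ``age`` is required in postmortem mode, ``group_truth`` enables
        validation metrics.
    mode
        ``"in_vivo"`` keeps low-T2 subjects as a reported LOW_T2 class;
        ``"postmortem"`` marks subjects failing eligibility (low T2 or age
        >= 65) INELIGIBLE and excludes them from validation metrics.

    Percentages are reported over the full cohort, rounded to the nearest
    integer; counts always sum to the cohort size.
    """
    if mode not in ("in_vivo", "postmortem"):
        raise ValueError(f"unknown mode {mode!r}")
    df = records.copy()
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if mode == "postmortem" and "age" not in df.columns:
        missing_cols.append("age")
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {missing_cols}")
    bad = df.index[df[list(_REQUIRED)].isna().any(axis=1)]
    if len(bad):
        ids = (df.loc[bad, "subject_id"].tolist()
               if "subject_id" in df.columns else list(bad))
        raise ValueError(f"records with missing lesion volumes: {ids}")

    labels = []
    for _, row in df.iterrows():
        if mode == "postmortem" and not eligibility(row["t2_ml"], row["age"], thresholds):
            labels.append(ClassLabel.INELIGIBLE)
        else:
            labels.append(classify_subject(row["t2_ml"], row["t1_ml"], thresholds))
    df["label"] = [lab.value for lab in labels]

    order = [ClassLabel.TMS, ClassLabel.MCMS, ClassLabel.LOW_T2, ClassLabel.INELIGIBLE]
    counts = {lab.value: int((df["label"] == lab.value).sum()) for lab in order}
    n = len(df)
    percentages = {k: (int(round(100.0 * v / n)) if n else 0) for k, v in counts.items()}

    result = StratificationResult(records=df, counts=counts, percentages=percentages)

    if "group_truth" in df.columns and mode == "postmortem":
        elig = df[df["label"] != ClassLabel.INELIGIBLE.value]
        truth_pos = elig["group_truth"].astype(str) == ClassLabel.MCMS.value
        pred_pos = elig["label"] == ClassLabel.MCMS.value
        cm = ConfusionMatrix(
            tp=int((truth_pos & pred_pos).sum()),
            fp=int((~truth_pos & pred_pos).sum()),
            fn=int((truth_pos & ~pred_pos).sum()),
            tn=int((~truth_pos & ~pred_pos).sum()),
        )
        result.confusion = cm
        if cm.tp + cm.fn > 0 and cm.tn + cm.fp > 0:
            result.sensitivity, result.specificity, result.accuracy = confusion_metrics(cm)
    return result
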