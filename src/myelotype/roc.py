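"""ROC analysis and Youden-optimal cutpoints for the subtype classifier.

The classifier's operating points (T1 volume < 0.75 ml, T1/T2% < 1.9%) come
from ROC curves in which MCMS is the positive class and *lower* metric
values indicate positivity.  This module builds such curves from raw scores,
computes the trapezoidal AUC (equal, with tie handling, to the Mann-Whitney
concordance probability), finds the cutpoint maximizing Youden's
J = sensitivity + specificity - 1, bootstraps AUC confidence intervals, and
sweeps the GM-threshold scaling factor k over a grid to pick the k whose
cutpoints best separate the groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROCCurve",
    "CutpointMetrics",
    "KGridResult",
    "roc_curve",
    "auc",
    "youden_optimal",
    "auc_ci_bootstrap",
    "k_grid_search",
    "DEFAULT_K_GRID",
]

#: The published grid of GM-SD scaling factors, 1.0 to 2.0 in 0.1 steps.
DEFAULT_K_GRID = tuple(np.round(np.arange(1.0, 2.01, 0.1), 1))


@dataclass
class ROCCurve:
    """Operating points over all distinct cutoffs of a score.

    ``cutoffs`` are ordered from the most permissive to the most stringent
    operating point and include -inf/+inf sentinels; tied scores share one
    operating point.  ``direction`` records whether low scores
    (``"lower_is_positive"``, the classifier's convention) or high scores
    flag the positive class.
    """

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_class: str
    direction: str
    n_pos: int
    n_neg: int

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    @property
    def tpr(self) -> np.ndarray:
        return self.sensitivity


@dataclass(frozen=True)
class CutpointMetrics:
    """One operating point: cutoff with its headline metrics."""

    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden_j: float


@dataclass
class KGridResult:
    """Per-k Youden cutpoints for T1 volume and T1/T2%, plus the selected k."""

    k_values: tuple[float, ...]
    t1_volume: dict[float, CutpointMetrics]
    ratio: dict[float, CutpointMetrics]
    selected_k: float
    criterion: str = "mean_accuracy"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.k_values:
            v, r = self.t1_volume[k], self.ratio[k]
            rows.append({
                "k": k,
                "t1vol_specificity": v.specificity, "t1vol_sensitivity": v.sensitivity,
                "t1vol_accuracy": v.accuracy, "t1vol_cutoff": v.cutoff,
                "ratio_specificity": r.specificity, "ratio_sensitivity": r.sensitivity,
                "ratio_accuracy": r.accuracy, "ratio_cutoff": r.cutoff,
            })
        return pd.DataFrame(rows)


def _validate_labels(labels, positive_class):
    lab = np.asarray(labels)
    pos = lab == positive_class
    if pos.all() or (~pos).all():
        raise ValueError("ROC needs both classes present")
    return pos


def roc_curve(scores, labels, direction: str = "lower_is_positive",
              positive_class="MCMS") -> ROCCurve:
    """Build a ROC curve from raw scores and class labels.

    Every distinct observed score appears as a cutoff (plus sentinels);
    with ``direction="lower_is_positive"`` a subject is called positive when
    its score is strictly below the cutoff.
    """
    if direction not in ("lower_is_positive", "higher_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    s = np.asarray(scores, dtype=float)
    pos = _validate_labels(labels, positive_class)
    if s.shape != pos.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())

    # Work with t = -score for lower_is_positive so "large t is positive";
    # then positive call at cutoff c means t > c.
    t = -s if direction == "lower_is_positive" else s
    uniq = np.unique(t)
    # Cutoffs between -inf sentinel (call everyone positive) and +inf.
    cut_t = np.concatenate(([-np.inf], uniq, [np.inf]))
    sens = np.empty(cut_t.size)
    spec = np.empty(cut_t.size)
    t_pos = np.sort(t[pos])
    t_neg = np.sort(t[~pos])
    for i, c in enumerate(cut_t):
        # predicted positive: t > c   (strict inequality, matching the
        # published "<" cutoffs on the original scale)
        tp = n_pos - np.searchsorted(t_pos, c, side="right")
        fp = n_neg - np.searchsorted(t_neg, c, side="right")
        sens[i] = tp / n_pos
        spec[i] = (n_neg - fp) / n_neg
    if direction == "lower_is_positive":
        cutoffs = -cut_t
    else:
        cutoffs = cut_t
    return ROCCurve(cutoffs=cutoffs, sensitivity=sens, specificity=spec,
                    positive_class=str(positive_class), direction=direction,
                    n_pos=n_pos, n_neg=n_neg)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the curve in (FPR, TPR) space.

    Equals the tie-adjusted Mann-Whitney concordance probability
    P(score_pos beats score_neg) + 0.5 P(tie).
    """
    order = np.argsort(curve.fpr, kind="stable")
    x = curve.fpr[order]
    y = curve.tpr[order]
    # stable-sort ties on fpr by tpr so the polyline is monotone
    for v in np.unique(x):
        sel = x == v
        y[sel] = np.sort(y[sel])
    return float(np.trapezoid(y, x))


def youden_optimal(curve: ROCCurve) -> CutpointMetrics:
    """Cutpoint maximizing J = sensitivity + specificity - 1.

    Ties on J break toward higher specificity, then toward the smaller
    cutoff.  Accuracy is computed from the curve's class counts at the
    selected operating point.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    # lexicographic: maximize (J, specificity, -cutoff)
    best = None
    for i in range(j.size):
        key = (j[i], curve.specificity[i], -curve.cutoffs[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    sens, spec = float(curve.sensitivity[i]), float(curve.specificity[i])
    acc = (sens * curve.n_pos + spec * curve.n_neg) / (curve.n_pos + curve.n_neg)
    return CutpointMetrics(cutoff=float(curve.cutoffs[i]), sensitivity=sens,
                           specificity=spec, accuracy=float(acc),
                           youden_j=float(j[i]))


def auc_ci_bootstrap(scores, labels, n_boot: int = 2000, seed: int = 0,
                     direction: str = "lower_is_positive",
                     positive_class="MCMS",
                     level: float = 0.95) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    Resamples positives and negatives separately so every replicate keeps
    both classes; deterministic for a fixed seed.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be unstable",
                      stacklevel=2)
    s = np.asarray(scores, dtype=float)
    pos = _validate_labels(labels, positive_class)
    s_pos, s_neg = s[pos], s[~pos]
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        rp = rng.choice(s_pos, size=s_pos.size, replace=True)
        rn = rng.choice(s_neg, size=s_neg.size, replace=True)
        bs = np.concatenate([rp, rn])
        bl = np.array([positive_class] * rp.size + ["__neg__"] * rn.size)
        stats[b] = auc(roc_curve(bs, bl, direction, positive_class))
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _youden_for(df: pd.DataFrame, col: str, positive_class: str) -> CutpointMetrics:
    return youden_optimal(roc_curve(df[col].to_numpy(), df["group_truth"].to_numpy(),
                                    "lower_is_positive", positive_class))


def k_grid_search(cohort_volumes_per_k: pd.DataFrame,
                  k_values=DEFAULT_K_GRID,
                  positive_class: str = "MCMS",
                  criterion: str = "mean_accuracy") -> KGridResult:
    """Sweep the GM-threshold scaling factor k over a grid.

    Parameters
    ----------
    cohort_volumes_per_k
        Tidy table with columns ``k, subject_id, group_truth, t1_ml,
        ratio_pct``: the T1 volume and T1/T2% of every subject re-measured
        at every k (each k changes the segmentation threshold, hence the
        volumes).
    k_values
        Grid to evaluate; every value must be present in the table.
    criterion
        ``"mean_accuracy"`` (default): select the k maximizing the mean of
        the two Youden-cutpoint accuracies, breaking ties toward higher
        T1/T2% specificity and finally by the median of the still-tied k
        values (the center of the optimal plateau, farthest from both
        failure modes of the threshold).  ``"ratio_accuracy"`` and
        ``"t1vol_accuracy"`` use a single metric's accuracy with the same
        tie handling.

    Returns one pair of cutpoints per k plus the selected k.
    """
    k_values = tuple(float(k) for k in k_values)
    if len(k_values) == 0:
        raise ValueError("empty k grid")
    if any(k2 <= k1 for k1, k2 in zip(k_values, k_values[1:])):
        raise ValueError("k values must be strictly increasing")
    table_ks = set(np.round(cohort_volumes_per_k["k"].unique(), 10))
    missing = [k for k in k_values if round(k, 10) not in table_ks]
    if missing:
        raise ValueError(f"cohort table lacks rows for k={missing}")

    t1_volume: dict[float, CutpointMetrics] = {}
    ratio: dict[float, CutpointMetrics] = {}
    for k in k_values:
        sub = cohort_volumes_per_k[np.isclose(cohort_volumes_per_k["k"], k)]
        t1_volume[k] = _youden_for(sub, "t1_ml", positive_class)
        ratio[k] = _youden_for(sub, "ratio_pct", positive_class)

    def score(k: float) -> tuple[float, float]:
        if criterion == "mean_accuracy":
            primary = 0.5 * (t1_volume[k].accuracy + ratio[k].accuracy)
        elif criterion == "ratio_accuracy":
            primary = ratio[k].accuracy
        elif criterion == "t1vol_accuracy":
            primary = t1_volume[k].accuracy
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        return (primary, ratio[k].specificity)

    best = max(score(k) for k in k_values)
    tied = [k for k in k_values if score(k) == best]
    selected = float(np.median(tied))
    if selected not in tied:  # even-sized plateau: take the lower middle
        selected = tied[(len(tied) - 1) // 2]
    return KGridResult(k_values=k_values, t1_volume=t1_volume, ratio=ratio,
                       selected_k=float(selected), criterion=criterion)
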