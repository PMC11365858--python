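"""Synthetic subject tables matching published cohort summary statistics.

Real per-subject lesion volumes are not deposited; this module draws
cohorts whose marginal distributions match the printed summaries (median
with quartiles, or mean with SD) for each subtype group.  Quartile
summaries are matched with a log-normal (lesion volumes are positive and
right-skewed; the family itself is a stand-in and is flagged in the
generated metadata), mean/SD summaries with a normal truncated at zero.

To avoid impossible records (T1 volume exceeding T2 volume), each group is
parameterized by its T2 volume together with *either* the T1/T2% ratio
(preferred: T1 is derived as T2 x ratio / 100, guaranteeing T1 <= T2) or
the T1 volume directly (then clipped to T2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LogNormalQuartiles",
    "TruncNormal",
    "GroupSpec",
    "CohortSpec",
    "quartiles_to_lognormal",
    "generate_cohort",
    "sprintms_cohort_spec",
    "postmortem_validation_spec",
    "development_cohort_spec",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = ("subject_id", "group_truth", "t2_ml", "t1_ml",
                  "ratio_pct", "age", "sequence")

_Z75 = float(sps.norm.ppf(0.75))  # 0.6744897...


def quartiles_to_lognormal(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and quartiles.

    mu = ln(median); sigma = (ln q3 - ln q1) / (2 * 0.67449).  The summary
    must satisfy 0 < q1 < median < q3; a degenerate spread (q1 = q3) is
    rejected.  The two-parameter family reproduces the median and the
    quartile ratio q3/q1 exactly; the individual quartiles are matched
    exactly only when they are log-symmetric about the median.
    """
    if min(median, q1, q3) <= 0:
        raise ValueError("log-normal quartile matching needs positive summaries")
    if not (q1 < median < q3):
        raise ValueError(f"need q1 < median < q3, got ({q1}, {median}, {q3})")
    mu = float(np.log(median))
    sigma = float((np.log(q3) - np.log(q1)) / (2.0 * _Z75))
    return mu, sigma


@dataclass(frozen=True)
class LogNormalQuartiles:
    """Positive quantity summarized as median (q1-q3)."""

    median: float
    q1: float
    q3: float

    def params(self) -> tuple[float, float]:
        return quartiles_to_lognormal(self.median, self.q1, self.q3)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mu, sigma = self.params()
        return np.exp(mu + sigma * rng.standard_normal(n))


@dataclass(frozen=True)
class TruncNormal:
    """Quantity summarized as mean (SD), truncated below at ``lower``."""

    mean: float
    sd: float
    lower: float = 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.sd == 0:
            return np.full(n, float(self.mean))
        a = (self.lower - self.mean) / self.sd
        u = rng.random(n)
        return sps.truncnorm.ppf(u, a, np.inf, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class GroupSpec:
    """One subtype group: sample size plus marginal distributions.

    Exactly one of ``ratio_pct`` / ``t1_ml`` must be given (see module
    docstring for how T1 <= T2 is enforced in each case).
    """

    name: str
    n: int
    t2_ml: LogNormalQuartiles | TruncNormal
    ratio_pct: LogNormalQuartiles | TruncNormal | None = None
    t1_ml: LogNormalQuartiles | TruncNormal | None = None
    age: TruncNormal = field(default_factory=lambda: TruncNormal(55.0, 8.0))
    sequence: str = "FLASH"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("sample size must be non-negative")
        if (self.ratio_pct is None) == (self.t1_ml is None):
            raise ValueError("give exactly one of ratio_pct or t1_ml")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0
    metadata: str = ("volume marginals matched by log-normal quartiles or "
                     "truncated normal; distribution family is a stand-in, "
                     "not reported with the source summaries")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one subject table, deterministic for a fixed seed.

    Returns a DataFrame with columns ``subject_id, group_truth, t2_ml,
    t1_ml, ratio_pct, age, sequence``; ``group_truth`` is the generating
    group's name.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    offset = 0
    for g in spec.groups:
        t2 = g.t2_ml.sample(rng, g.n)
        t2 = np.maximum(t2, 1e-9)
        if g.ratio_pct is not None:
            ratio = np.clip(g.ratio_pct.sample(rng, g.n), 0.0, 100.0)
            t1 = t2 * ratio / 100.0
        else:
            t1 = np.clip(g.t1_ml.sample(rng, g.n), 0.0, t2)
            ratio = 100.0 * t1 / t2
        age = g.age.sample(rng, g.n)
        frames.append(pd.DataFrame({
            "subject_id": [f"S{offset + i:04d}" for i in range(g.n)],
            "group_truth": g.name,
            "t2_ml": t2,
            "t1_ml": t1,
            "ratio_pct": ratio,
            "age": age,
            "sequence": g.sequence,
        }))
        offset += g.n
    if not frames:
        return pd.DataFrame(columns=list(COHORT_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def sprintms_cohort_spec(seed: int = 0, n_scale: float = 1.0) -> CohortSpec:
    """In-vivo progressive-MS trial cohort: 199 TMS / 25 MCMS / 31 low-T2.

    T2 volume and T1/T2% summaries are the published per-group medians and
    IQRs; ages the published means/SDs.  ``n_scale`` multiplies the group
    sizes (rounded) for larger synthetic draws.
    """
    def n_of(n):
        return int(round(n * n_scale))
    return CohortSpec(groups=(
        GroupSpec("TMS", n_of(199),
                  t2_ml=LogNormalQuartiles(11.95, 5.32, 22.71),
                  ratio_pct=LogNormalQuartiles(6.15, 3.94, 11.31),
                  age=TruncNormal(55.7, 7.3)),
        GroupSpec("MCMS", n_of(25),
                  t2_ml=LogNormalQuartiles(8.70, 3.82, 17.13),
                  ratio_pct=LogNormalQuartiles(1.00, 0.54, 1.69),
                  age=TruncNormal(56.7, 6.5)),
        GroupSpec("LOW_T2", n_of(31),
                  t2_ml=LogNormalQuartiles(1.55, 1.17, 1.78),
                  ratio_pct=LogNormalQuartiles(3.87, 1.75, 7.01),
                  age=TruncNormal(53.8, 7.7)),
    ), seed=seed)


def postmortem_validation_spec(seed: int = 0, n_scale: float = 1.0) -> CohortSpec:
    """Postmortem validation cohort: 29 TMS / 7 MCMS, published summaries."""
    def n_of(n):
        return int(round(n * n_scale))
    return CohortSpec(groups=(
        GroupSpec("TMS", n_of(29),
                  t2_ml=TruncNormal(47.40, 27.45, lower=2.0),
                  t1_ml=LogNormalQuartiles(2.49, 0.80, 5.45),
                  age=TruncNormal(55.0, 7.4)),
        GroupSpec("MCMS", n_of(7),
                  t2_ml=TruncNormal(35.24, 15.51, lower=2.0),
                  t1_ml=LogNormalQuartiles(0.12, 0.07, 0.32),
                  age=TruncNormal(56.0, 6.7)),
    ), seed=seed)


def development_cohort_spec(seed: int = 0, n_scale: float = 1.0) -> CohortSpec:
    """Characterized development cohort: 12 TMS / 10 MCMS, published summaries.

    T1 volume is given by its published median/IQR; the ratio follows from
    the drawn pair.
    """
    def n_of(n):
        return int(round(n * n_scale))
    return CohortSpec(groups=(
        GroupSpec("TMS", n_of(12),
                  t2_ml=TruncNormal(43.81, 27.06, lower=2.0),
                  t1_ml=LogNormalQuartiles(1.95, 0.63, 10.52),
                  age=TruncNormal(55.0, 8.0)),
        GroupSpec("MCMS", n_of(10),
                  t2_ml=TruncNormal(23.08, 12.98, lower=2.0),
                  t1_ml=LogNormalQuartiles(0.265, 0.067, 0.722),
                  age=TruncNormal(55.0, 8.0)),
    ), seed=seed)
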