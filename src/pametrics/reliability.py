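"""Test-retest reliability statistics for paired questionnaire scores.

The agreement model is a one-way random-effects decomposition: each subject
has a true score drawn from a between-subject distribution, and each of the
two administrations (T0, T1) adds independent measurement error.  From the
resulting variance components this module derives

* the intraclass correlation coefficient ICC(1,1) — between-subject variance
  as a fraction of total variance — with its exact F-based 95% CI,
* the standard error of measurement, SEM = sqrt(error variance),
* the smallest detectable difference, SDD95 = 1.96 * sqrt(2) * SEM,
* the observed 95% score range (2.5th to 97.5th percentile, T0 and T1
  pooled), the SDD95/range95 ratio, and the number of distinguishable
  steps the instrument resolves on that range.

Negative between-subject variance estimates are truncated to zero for the
SEM-related quantities, but the raw (possibly negative) ICC is reported
as-is, so a near-zero true subject effect shows up as a small negative ICC
rather than being silently clamped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedScores",
    "VarianceComponents",
    "ReliabilityResult",
    "variance_components",
    "icc_oneway",
    "sem_sdd",
    "sdd95_from_sem",
    "range95",
    "distinguishable_steps",
    "rate_icc",
    "analyze_paired",
    "reliability_table",
]

#: SDD95 multiplier: 95% two-sided normal quantile times sqrt(2) for the
#: variance of a difference of two equally noisy measurements.
SDD_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass
class PairedScores:
    """One score measured twice (T0, T1) on the same subjects."""

    name: str
    subjects: list[str]
    t0: np.ndarray
    t1: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.t0 = np.asarray(self.t0, dtype=float)
        self.t1 = np.asarray(self.t1, dtype=float)
        if not (len(self.subjects) == self.t0.size == self.t1.size):
            raise ValueError("subjects, t0 and t1 must have equal length")

    def complete(self) -> "PairedScores":
        """Drop subjects with a missing value at either visit."""
        ok = np.isfinite(self.t0) & np.isfinite(self.t1)
        if not ok.all():
            dropped = [s for s, k in zip(self.subjects, ok) if not k]
            warnings.warn(
                f"{self.name}: excluding {len(dropped)} incomplete pair(s): "
                f"{dropped}",
                stacklevel=2,
            )
        return PairedScores(
            self.name,
            [s for s, k in zip(self.subjects, ok) if k],
            self.t0[ok],
            self.t1[ok],
            self.units,
        )

    @property
    def n(self) -> int:
        return self.t0.size

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, score: str, units: str = ""
    ) -> "PairedScores":
        """Build from a long table with columns subject, visit, score, value."""
        sub = df[df["score"] == score]
        wide = sub.pivot_table(
            index="subject", columns="visit", values="value", aggfunc="first"
        )
        for visit in ("T0", "T1"):
            if visit not in wide.columns:
                wide[visit] = np.nan
        wide = wide.sort_index()
        return cls(
            score,
            [str(s) for s in wide.index],
            wide["T0"].to_numpy(),
            wide["T1"].to_numpy(),
            units,
        )


@dataclass
class VarianceComponents:
    """One-way ANOVA mean squares and variance components (k replicates)."""

    msb: float
    msw: float
    between_var: float  # max(0, (MSB - MSW)/k)
    error_var: float  # MSW
    n: int
    k: int = 2


@dataclass
class ReliabilityResult:
    name: str
    n: int
    icc: float
    icc_ci95: tuple[float, float]
    sem: float
    sdd95: float
    range95: float
    ratio: Optional[float]
    steps: Optional[int]
    rating: str
    clinically_useful: Optional[bool]
    median_t0: float = math.nan
    iqr_t0: tuple[float, float] = field(default=(math.nan, math.nan))
    median_t1: float = math.nan
    iqr_t1: tuple[float, float] = field(default=(math.nan, math.nan))


def variance_components(p: PairedScores) -> VarianceComponents:
    """One-way random-effects ANOVA with subjects as the grouping factor.

    With n subjects and k=2 administrations:
    ``MSW = sum_ij (x_ij - xbar_i)^2 / (n (k-1))`` and
    ``MSB = k * sum_i (xbar_i - xbar)^2 / (n - 1)``.
    """
    p = p.complete()
    if p.n < 2:
        raise ValueError(
            f"{p.name}: need at least 2 complete pairs, got {p.n}"
        )
    x = np.stack([p.t0, p.t1], axis=1)
    n, k = x.shape
    subject_means = x.mean(axis=1)
    grand = x.mean()
    msw = float(((x - subject_means[:, None]) ** 2).sum() / (n * (k - 1)))
    msb = float(k * ((subject_means - grand) ** 2).sum() / (n - 1))
    return VarianceComponents(
        msb=msb,
        msw=msw,
        between_var=max(0.0, (msb - msw) / k),
        error_var=msw,
        n=n,
        k=k,
    )


def icc_oneway(
    v: VarianceComponents, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """ICC(1,1) point estimate with the exact one-way F confidence interval.

    ICC = (MSB - MSW) / (MSB + (k-1) MSW).  The interval transforms the
    F ratio MSB/MSW with (n-1, n(k-1)) degrees of freedom through the
    standard one-way bounds.  A zero MSW (perfect agreement) degenerates
    to ICC = 1 with interval [1, 1].
    """
    n, k = v.n, v.k
    if v.msw == 0.0:
        if v.msb == 0.0:
            # all observations identical: subject effect undefined
            return math.nan, (math.nan, math.nan)
        return 1.0, (1.0, 1.0)
    icc = (v.msb - v.msw) / (v.msb + (k - 1) * v.msw)
    f_obs = v.msb / v.msw
    df1, df2 = n - 1, n * (k - 1)
    f_upper = stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
    f_lower = stats.f.ppf(1.0 - alpha / 2.0, df2, df1)
    fl = f_obs / f_upper
    fu = f_obs * f_lower
    lo = (fl - 1.0) / (fl + k - 1.0)
    hi = (fu - 1.0) / (fu + k - 1.0)
    return float(icc), (float(lo), float(hi))


def sem_sdd(v: VarianceComponents) -> tuple[float, float]:
    """SEM = sqrt(error variance); SDD95 = 1.96 * sqrt(2) * SEM."""
    sem = math.sqrt(v.error_var)
    return sem, sdd95_from_sem(sem)


def sdd95_from_sem(sem: float) -> float:
    """Smallest detectable difference at 95% confidence for a given SEM."""
    if sem < 0:
        raise ValueError("SEM must be non-negative")
    return SDD_FACTOR * sem


def range95(values: Sequence[float] | np.ndarray) -> float:
    """Observed 95% range: 97.5th minus 2.5th percentile (linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("range95 needs at least 2 observations")
    lo, hi = np.percentile(arr, [2.5, 97.5], method="linear")
    return float(hi - lo)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def distinguishable_steps(ratio: float) -> int:
    """Number of SDD-sized steps on the observed range, round(1/ratio).

    Rounds half away from zero; e.g. a ratio of 0.40 resolves 3 steps.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return _round_half_away(1.0 / ratio)


def rate_icc(icc: float) -> str:
    """Qualitative ICC label: poor < 0.40 <= fair < 0.60 <= good < 0.75 <= excellent."""
    if not math.isfinite(icc):
        return "undefined"
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def analyze_paired(p: PairedScores, alpha: float = 0.05) -> ReliabilityResult:
    """Full test-retest reliability bundle for one paired score."""
    p = p.complete()
    v = variance_components(p)
    icc, ci = icc_oneway(v, alpha=alpha)
    sem, sdd = sem_sdd(v)
    pooled = np.concatenate([p.t0, p.t1])
    rng95 = range95(pooled)
    if rng95 == 0.0:
        warnings.warn(f"{p.name}: zero observed range; ratio undefined")
        ratio: Optional[float] = None
        steps: Optional[int] = None
        useful: Optional[bool] = None
    else:
        ratio = sdd / rng95
        steps = distinguishable_steps(ratio) if ratio > 0 else None
        useful = ratio <= 0.20
    q = np.percentile
    return ReliabilityResult(
        name=p.name,
        n=p.n,
        icc=icc,
        icc_ci95=ci,
        sem=sem,
        sdd95=sdd,
        range95=rng95,
        ratio=ratio,
        steps=steps,
        rating=rate_icc(icc),
        clinically_useful=useful,
        median_t0=float(np.median(p.t0)),
        iqr_t0=(float(q(p.t0, 25)), float(q(p.t0, 75))),
        median_t1=float(np.median(p.t1)),
        iqr_t1=(float(q(p.t1, 25)), float(q(p.t1, 75))),
    )


def reliability_table(
    scores: pd.DataFrame, score_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Test-retest reliability table from a long scores frame.

    ``scores`` has columns subject, visit (T0/T1), score, value.  One row
    per score: medians and quartiles per visit, ICC (95% CI), SEM, SDD95,
    SDD95/range95 ratio, distinguishable steps and the qualitative rating.
    """
    if score_names is None:
        score_names = list(dict.fromkeys(scores["score"]))
    rows = []
    for name in score_names:
        p = PairedScores.from_dataframe(scores, name)
        r = analyze_paired(p)
        rows.append(
            {
                "score": name,
                "n": r.n,
                "median_t0": r.median_t0,
                "p25_t0": r.iqr_t0[0],
                "p75_t0": r.iqr_t0[1],
                "median_t1": r.median_t1,
                "p25_t1": r.iqr_t1[0],
                "p75_t1": r.iqr_t1[1],
                "icc": r.icc,
                "icc_ci_low": r.icc_ci95[0],
                "icc_ci_high": r.icc_ci95[1],
                "sem": r.sem,
                "sdd95": r.sdd95,
                "range95": r.range95,
                "sdd_range_ratio": r.ratio,
                "steps": r.steps,
                "rating": r.rating,
                "clinically_useful": r.clinically_useful,
            }
        )
    return pd.DataFrame(rows)
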