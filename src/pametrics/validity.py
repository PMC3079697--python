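"""Construct validity of questionnaire scores against accelerometry.

Self-reported activity has no gold standard, so construct validity is
assessed by agreement with a hip-worn accelerometer: Spearman rank
correlations between questionnaire totals and overall counts/min, and
intraclass correlations (one-way, the questionnaire and the accelerometer
treated as two replicate measurements of the same quantity) for outcomes
that share units (min/week).  A correlation of at least 0.50 is flagged as
adequate, following the convention in systematic reviews of
physical-activity questionnaires.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reliability import PairedScores, icc_oneway, variance_components

__all__ = [
    "ValidityResult",
    "spearman",
    "agreement_icc",
    "acsm_compliance",
    "descriptives",
    "response_rate",
    "ADEQUATE_CORRELATION",
    "ACSM_MODERATE_MIN_PER_WK",
]

ADEQUATE_CORRELATION = 0.50
ACSM_MODERATE_MIN_PER_WK = 150.0


@dataclass
class ValidityResult:
    name: str
    n_included: int
    spearman_rho: Optional[float] = None
    p_value: Optional[float] = None
    adequate: Optional[bool] = None
    icc: Optional[float] = None
    icc_ci95: Optional[tuple[float, float]] = None


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    permutation: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The default p-value uses the t approximation with n-2 degrees of
    freedom.  ``permutation=N`` instead estimates p by permuting one
    variable N times (N >= 10000 recommended); ``permutation=0`` enumerates
    all n! orderings exactly (only sensible for tiny n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("constant input: Spearman correlation undefined")
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if permutation is None:
        return rho, float(p)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def _rho(ryp: np.ndarray) -> float:
        return float(np.corrcoef(rx, ryp)[0, 1])

    obs = abs(_rho(ry))
    if permutation == 0:
        stats_all = [abs(_rho(np.asarray(perm))) for perm in permutations(ry)]
        p_perm = float(np.mean([s >= obs - 1e-12 for s in stats_all]))
    else:
        rng = rng or np.random.default_rng()
        hits = 1  # include the observed ordering
        for _ in range(permutation):
            hits += abs(_rho(rng.permutation(ry))) >= obs - 1e-12
        p_perm = hits / (permutation + 1)
    return rho, p_perm


def agreement_icc(
    a: Sequence[float], b: Sequence[float], name: str = "agreement"
) -> tuple[float, tuple[float, float]]:
    """One-way ICC treating the two instruments as replicate measurements.

    Same machinery as test-retest reliability: absolute agreement between
    instrument ``a`` and instrument ``b`` readings in shared units.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    p = PairedScores(name, [str(i) for i in range(a.size)], a, b)
    return icc_oneway(variance_components(p))


def acsm_compliance(moderate_min_per_wk: Sequence[float]) -> Optional[float]:
    """Fraction of subjects below 150 min/week of moderate-intensity activity.

    Returns the non-compliance fraction (subjects failing the ACSM
    recommendation); exactly 150 min/week counts as compliant.  ``None``
    for empty input.
    """
    arr = np.asarray(moderate_min_per_wk, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        warnings.warn("no subjects: compliance undefined")
        return None
    if (arr < 0).any():
        raise ValueError("minutes/week must be non-negative")
    return float((arr < ACSM_MODERATE_MIN_PER_WK).mean())


def descriptives(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, 25th, 75th percentile) with linear interpolation."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 1:
        raise ValueError("descriptives need at least one value")
    med, p25, p75 = np.percentile(arr, [50, 25, 75], method="linear")
    return float(med), float(p25), float(p75)


def response_rate(n_participating: int, n_eligible: int) -> float:
    """Study response rate in percent, rounded to the nearest percent."""
    if n_eligible <= 0 or n_participating < 0 or n_participating > n_eligible:
        raise ValueError("invalid counts")
    return round(100.0 * n_participating / n_eligible)


def validity_table(
    scores: pd.DataFrame,
    accel: pd.DataFrame,
    correlate: Sequence[tuple[str, str]] = (),
    agree: Sequence[tuple[str, str]] = (),
    visit: str = "T0",
) -> pd.DataFrame:
    """Construct-validity table: questionnaire scores vs accelerometer summaries.

    ``scores`` is the long frame (subject, visit, score, value); ``accel``
    the subject-summary frame from :func:`pametrics.accel.summaries_to_frame`.
    ``correlate`` pairs (score name, accel column) are compared by Spearman
    correlation; ``agree`` pairs by one-way agreement ICC.  Only subjects
    with ``included=True`` accelerometer data enter the analysis.
    """
    acc = accel[accel["included"]].set_index("subject")
    sc = scores[scores["visit"] == visit].pivot_table(
        index="subject", columns="score", values="value", aggfunc="first"
    )
    sc.index = sc.index.astype(str)
    acc.index = acc.index.astype(str)
    common = sc.index.intersection(acc.index)
    rows = []
    for score_name, col in correlate:
        x = sc.loc[common, score_name].to_numpy()
        y = acc.loc[common, col].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        rho, p = spearman(x[ok], y[ok])
        rows.append(
            {
                "score": score_name,
                "accel_measure": col,
                "statistic": "spearman",
                "n": int(ok.sum()),
                "value": rho,
                "p_value": p,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "adequate": bool(rho >= ADEQUATE_CORRELATION)
                if math.isfinite(rho)
                else None,
            }
        )
    for score_name, col in agree:
        x = sc.loc[common, score_name].to_numpy()
        y = acc.loc[common, col].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        icc, ci = agreement_icc(x[ok], y[ok], name=f"{score_name}~{col}")
        rows.append(
            {
                "score": score_name,
                "accel_measure": col,
                "statistic": "icc",
                "n": int(ok.sum()),
                "value": icc,
                "p_value": np.nan,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "adequate": bool(icc >= ADEQUATE_CORRELATION)
                if math.isfinite(icc)
                else None,
            }
        )
    return pd.DataFrame(rows)
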