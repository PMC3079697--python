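"""Accelerometer epoch processing: wear time, intensity bands, weekly summaries.

The input is a uniaxial ActiGraph-style stream of 15-second epoch counts.
Processing follows the conventional hip-worn actigraphy pipeline:

1. epochs are aggregated to counts/min (4 epochs per minute),
2. non-wear is any maximal run of >= 60 consecutive zero-count minutes,
3. wear minutes are classified with the Freedson uniaxial cut-points
   (< 100 sedentary, 100-1951 light, 1952-5724 moderate, >= 5725 vigorous
   counts/min),
4. a day is valid with >= 600 wear minutes; a subject is included with
   >= 5 valid days; weekly totals are the mean over valid days times 7.

Non-wear minutes are excluded from every band (wear-time-only accounting),
so per-day band minutes always sum to that day's wear minutes.  An optional
journal mask (self-reported off-body intervals) can force minutes to
non-wear before summarising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EpochSeries",
    "MinuteSeries",
    "CutPoints",
    "DaySummary",
    "SubjectSummary",
    "BANDS",
    "to_minutes",
    "detect_nonwear",
    "apply_journal_mask",
    "classify_band",
    "classify_bands",
    "day_summaries",
    "summarize_subject",
    "read_epoch_csv",
    "write_epoch_csv",
    "read_journal_csv",
]

BANDS = ("sedentary", "light", "moderate", "vigorous")

EPOCHS_PER_MINUTE = 4
MIN_NONWEAR_MINUTES = 60
MIN_WEAR_MINUTES_VALID_DAY = 600
MIN_VALID_DAYS_INCLUDED = 5


@dataclass
class EpochSeries:
    """Uniform 15-s epoch count stream for one subject."""

    subject: str
    start: pd.Timestamp
    counts: np.ndarray
    epoch_seconds: int = 15

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("epoch counts must be non-negative")

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.counts.size) * self.epoch_seconds, unit="s"
        )


@dataclass
class MinuteSeries:
    """Counts/min with wear flags; one entry per minute."""

    subject: str
    start: pd.Timestamp
    counts_per_min: np.ndarray
    wear: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.counts_per_min = np.asarray(self.counts_per_min)
        if self.wear is None:
            self.wear = np.ones(self.counts_per_min.size, dtype=bool)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.wear.size != self.counts_per_min.size:
            raise ValueError("wear flags must match counts length")

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.counts_per_min.size), unit="min"
        )


@dataclass(frozen=True)
class CutPoints:
    """Counts/min thresholds separating the four intensity bands."""

    light_low: int = 100
    moderate_low: int = 1952
    vigorous_low: int = 5725

    def __post_init__(self) -> None:
        if not 0 < self.light_low < self.moderate_low < self.vigorous_low:
            raise ValueError("cut-points must be strictly increasing and > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CutPoints":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            light_low=int(raw["light_low"]),
            moderate_low=int(raw["moderate_low"]),
            vigorous_low=int(raw["vigorous_low"]),
        )


@dataclass
class DaySummary:
    date: pd.Timestamp
    wear_minutes: int
    band_minutes: dict[str, int]
    total_counts: int
    valid: bool


@dataclass
class SubjectSummary:
    subject: str
    n_days: int
    n_valid_days: int
    included: bool
    counts_per_min_overall: float
    weekly_band_minutes: dict[str, float]
    total_pa_min_per_wk: float
    sedentary_min_per_wk: float
    days: list[DaySummary]


def to_minutes(s: EpochSeries) -> MinuteSeries:
    """Aggregate 15-s epochs to counts/min (sum of 4 consecutive epochs).

    The stream is first trimmed to start at a minute boundary; a trailing
    partial minute is dropped with a warning.
    """
    if s.epoch_seconds != 15:
        raise ValueError("to_minutes expects 15-second epochs")
    counts = s.counts
    start = s.start
    offset_s = (start.second + 60 * 0) % 60
    if offset_s % s.epoch_seconds != 0:
        raise ValueError("stream start is not epoch-aligned")
    lead = (60 - offset_s) % 60 // s.epoch_seconds
    if lead:
        counts = counts[lead:]
        start = start + pd.Timedelta(seconds=lead * s.epoch_seconds)
    tail = counts.size % EPOCHS_PER_MINUTE
    if tail:
        warnings.warn(
            f"{s.subject}: dropping trailing partial minute of {tail} epoch(s)"
        )
        counts = counts[: counts.size - tail]
    cpm = counts.reshape(-1, EPOCHS_PER_MINUTE).sum(axis=1)
    return MinuteSeries(s.subject, start, cpm)


def _zero_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zeros as (start, stop) half-open index pairs."""
    iszero = np.concatenate(([False], x == 0, [False]))
    d = np.diff(iszero.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_nonwear(
    m: MinuteSeries, min_duration: int = MIN_NONWEAR_MINUTES
) -> MinuteSeries:
    """Flag non-wear: every maximal zero-count run of >= ``min_duration`` minutes.

    The whole maximal run is flagged, not just its first hour.  Shorter zero
    runs stay wear (no spike-tolerance allowance).  Idempotent.
    """
    wear = np.ones(m.counts_per_min.size, dtype=bool)
    for start, stop in _zero_runs(m.counts_per_min):
        if stop - start >= min_duration:
            wear[start:stop] = False
    return MinuteSeries(m.subject, m.start, m.counts_per_min, wear)


def apply_journal_mask(
    m: MinuteSeries, intervals: Iterable[tuple[pd.Timestamp, pd.Timestamp]]
) -> MinuteSeries:
    """Force journal-reported off-body intervals to non-wear."""
    ts = m.timestamps
    wear = m.wear.copy()
    for start, end in intervals:
        wear[(ts >= pd.Timestamp(start)) & (ts < pd.Timestamp(end))] = False
    return MinuteSeries(m.subject, m.start, m.counts_per_min, wear)


def classify_band(counts_per_min: float, cp: CutPoints = CutPoints()) -> str:
    """Intensity band for one counts/min value."""
    if counts_per_min < 0:
        raise ValueError("counts/min must be non-negative")
    if counts_per_min < cp.light_low:
        return "sedentary"
    if counts_per_min < cp.moderate_low:
        return "light"
    if counts_per_min < cp.vigorous_low:
        return "moderate"
    return "vigorous"


def classify_bands(
    counts_per_min: np.ndarray, cp: CutPoints = CutPoints()
) -> np.ndarray:
    """Vectorised band index (0..3 into :data:`BANDS`) per minute."""
    cpm = np.asarray(counts_per_min)
    if (cpm < 0).any():
        raise ValueError("counts/min must be non-negative")
    edges = np.array([cp.light_low, cp.moderate_low, cp.vigorous_low])
    return np.searchsorted(edges, cpm, side="right")


def day_summaries(m: MinuteSeries, cp: CutPoints = CutPoints()) -> list[DaySummary]:
    """Per calendar-day wear and band minutes (wear-time-only accounting)."""
    ts = m.timestamps
    days = pd.Series(ts.floor("D"))
    band_idx = classify_bands(m.counts_per_min, cp)
    out: list[DaySummary] = []
    for day, idx in days.groupby(days).groups.items():
        sel = np.asarray(idx)
        wear = m.wear[sel]
        wear_min = int(wear.sum())
        bidx = band_idx[sel][wear]
        band_minutes = {
            band: int((bidx == i).sum()) for i, band in enumerate(BANDS)
        }
        out.append(
            DaySummary(
                date=pd.Timestamp(day),
                wear_minutes=wear_min,
                band_minutes=band_minutes,
                total_counts=int(m.counts_per_min[sel][wear].sum()),
                valid=wear_min >= MIN_WEAR_MINUTES_VALID_DAY,
            )
        )
    out.sort(key=lambda d: d.date)
    return out


def summarize_subject(
    m: MinuteSeries,
    cp: CutPoints = CutPoints(),
    min_wear_minutes: int = MIN_WEAR_MINUTES_VALID_DAY,
    min_valid_days: int = MIN_VALID_DAYS_INCLUDED,
) -> SubjectSummary:
    """Weekly subject summary over valid days.

    Weekly band minutes are the mean over valid days times 7; the overall
    counts/min is total counts over wear minutes divided by wear minutes,
    both restricted to valid days.  Subjects with fewer than
    ``min_valid_days`` valid days are returned with ``included=False`` and
    NaN weekly quantities (downstream analyses exclude them).
    """
    days = day_summaries(m, cp)
    for d in days:
        d.valid = d.wear_minutes >= min_wear_minutes
    valid = [d for d in days if d.valid]
    included = len(valid) >= min_valid_days
    if valid:
        weekly = {
            band: 7.0 * float(np.mean([d.band_minutes[band] for d in valid]))
            for band in BANDS
        }
        wear_total = sum(d.wear_minutes for d in valid)
        cpm = (
            sum(d.total_counts for d in valid) / wear_total
            if wear_total
            else float("nan")
        )
    else:
        weekly = {band: float("nan") for band in BANDS}
        cpm = float("nan")
    return SubjectSummary(
        subject=m.subject,
        n_days=len(days),
        n_valid_days=len(valid),
        included=included,
        counts_per_min_overall=float(cpm),
        weekly_band_minutes=weekly,
        total_pa_min_per_wk=weekly["light"] + weekly["moderate"] + weekly["vigorous"],
        sedentary_min_per_wk=weekly["sedentary"],
        days=days,
    )


def read_epoch_csv(path: str | Path, subject: Optional[str] = None) -> EpochSeries:
    """Read an epoch CSV with columns ``timestamp`` (ISO-8601) and ``axis1``.

    Timestamps must be uniformly spaced at 15 s with no gaps.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if df.empty:
        raise ValueError(f"{path}: empty epoch file")
    ts = pd.DatetimeIndex(df["timestamp"])
    deltas = np.diff(ts.asi8) / 1e9
    if deltas.size and not np.all(deltas == 15):
        raise ValueError(f"{path}: timestamps are not uniform 15-s epochs")
    return EpochSeries(
        subject=subject or Path(path).stem,
        start=ts[0],
        counts=df["axis1"].to_numpy(dtype=np.int64),
    )


def write_epoch_csv(s: EpochSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M:%S"), "axis1": s.counts}
    ).to_csv(path, index=False)


def read_journal_csv(
    path: str | Path,
) -> dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]]:
    """Journal CSV (subject, start, end[, reason]) to per-subject intervals."""
    df = pd.read_csv(path, parse_dates=["start", "end"])
    out: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["subject"]), []).append((row["start"], row["end"]))
    return out


def summaries_to_frame(summaries: Sequence[SubjectSummary]) -> pd.DataFrame:
    """Tabular view of subject summaries (one row per subject)."""
    rows = []
    for s in summaries:
        row = {
            "subject": s.subject,
            "n_days": s.n_days,
            "n_valid_days": s.n_valid_days,
            "included": s.included,
            "counts_per_min": s.counts_per_min_overall,
            "total_pa_min_per_wk": s.total_pa_min_per_wk,
            "mvpa_min_per_wk": s.weekly_band_minutes["moderate"]
            + s.weekly_band_minutes["vigorous"],
            "sedentary_min_per_wk": s.sedentary_min_per_wk,
        }
        for band in BANDS:
            row[f"{band}_min_per_wk"] = s.weekly_band_minutes[band]
        rows.append(row)
    return pd.DataFrame(rows)
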