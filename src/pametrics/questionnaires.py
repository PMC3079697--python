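"""Scoring for the AQuAA and PASE physical-activity recall questionnaires.

AQuAA (Activity Questionnaire for Adults and Adolescents)
    A 7-day recall of activities in five categories (commuting, work/school,
    household, leisure, sports); each entry carries days/week, minutes/day
    and a perceived intensity.  Each entry is assigned an energy cost in
    METs from a configurable lookup table and contributes
    ``days_per_week * minutes_per_day`` weekly minutes to one of four
    intensity bands: sedentary (< 2 METs), light [2, 4), moderate [4, 6.5)
    and vigorous (>= 6.5 METs).  The total score is the MET-weighted sum of
    weekly minutes over entries of at least 2 METs (MET*min/week).

    Band edges are half-open and lower-inclusive, which keeps the "< 2 MET
    is sedentary" rule exact.  How perceived intensity should interact with
    a compendium MET value is not standardised; here the lookup table is
    keyed on (activity, intensity) so perceived intensity selects among
    plausible MET values, with per-category fallbacks for unknown tokens.

PASE (Physical Activity Scale for the Elderly)
    Leisure and household items are answered on ordinal frequency
    (never / seldom / sometimes / often) and duration (< 1 h / 1-2 h /
    2-4 h / > 4 h) scales; paid or volunteer work is recorded in weekly
    hour categories.  Category midpoints convert answers to hours/week and
    the sum score is the weighted sum over items, using the externally
    published item weights (supplied via configuration, never invented
    here).  Work that involves mostly sitting contributes to sedentary
    minutes instead of the weighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml

__all__ = [
    "AQUAA_CATEGORIES",
    "AquaaEntry",
    "AquaaResponse",
    "AquaaScores",
    "MetTable",
    "PaseItem",
    "PaseWork",
    "PaseResponse",
    "PaseWeights",
    "PaseScores",
    "met_intensity_band",
    "score_aquaa",
    "pase_hours_per_week",
    "score_pase",
    "default_met_table",
    "default_pase_weights",
]

AQUAA_CATEGORIES = ("commuting", "work_school", "household", "leisure", "sports")
INTENSITIES = ("low", "medium", "high")
PASE_FREQUENCIES = ("never", "seldom", "sometimes", "often")
PASE_DURATIONS = ("lt1h", "h1to2", "h2to4", "gt4h")
PASE_WORK_HOURS = ("lt1h", "h1to4", "h5to8", "gt8h")

Intensity = Literal["low", "medium", "high"]


class ScoringError(ValueError):
    """Raised when a response cannot be scored with the given configuration."""


# ---------------------------------------------------------------------------
# AQuAA


@dataclass
class AquaaEntry:
    category: str
    activity: str
    days_per_week: int
    minutes_per_day: float
    intensity: Intensity

    def __post_init__(self) -> None:
        if self.category not in AQUAA_CATEGORIES:
            raise ValueError(f"unknown AQuAA category: {self.category!r}")
        if not 0 <= self.days_per_week <= 7:
            raise ValueError("days_per_week must be in [0, 7]")
        if self.minutes_per_day < 0:
            raise ValueError("minutes_per_day must be non-negative")
        if self.intensity not in INTENSITIES:
            raise ValueError(f"unknown intensity: {self.intensity!r}")

    @property
    def weekly_minutes(self) -> float:
        return self.days_per_week * self.minutes_per_day


@dataclass
class AquaaResponse:
    subject: str
    visit: str
    entries: list[AquaaEntry] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "visit": self.visit,
            "entries": [
                {
                    "category": e.category,
                    "activity": e.activity,
                    "days_per_week": e.days_per_week,
                    "minutes_per_day": e.minutes_per_day,
                    "intensity": e.intensity,
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AquaaResponse":
        entries = []
        for e in d.get("entries", []):
            e = dict(e)
            # hours+minutes duration entry is normalised to minutes here
            if "hours_per_day" in e:
                e["minutes_per_day"] = (
                    60.0 * e.pop("hours_per_day") + e.pop("minutes_per_day", 0.0)
                )
            entries.append(AquaaEntry(**e))
        return cls(subject=d["subject"], visit=d["visit"], entries=entries)


@dataclass
class AquaaScores:
    total_score: float  # MET*min/week over entries with MET >= 2
    sedentary_min: float
    light_min: float
    moderate_min: float
    vigorous_min: float

    @property
    def total_pa_min(self) -> float:
        """Weekly minutes of all at-least-light activity."""
        return self.light_min + self.moderate_min + self.vigorous_min

    @property
    def mvpa_min(self) -> float:
        """Weekly moderate-to-vigorous minutes."""
        return self.moderate_min + self.vigorous_min


@dataclass
class MetTable:
    """(activity, intensity) -> MET lookup with per-category fallbacks."""

    activities: dict[str, dict[str, float]]
    category_fallback: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for cat in AQUAA_CATEGORIES:
            if cat not in self.category_fallback:
                raise ValueError(f"MET table lacks fallback for category {cat!r}")
        for mapping in (*self.activities.values(), *self.category_fallback.values()):
            if any(v <= 0 for v in mapping.values()):
                raise ValueError("MET values must be positive")

    def lookup(self, entry: AquaaEntry) -> float:
        by_act = self.activities.get(entry.activity)
        if by_act is not None and entry.intensity in by_act:
            return by_act[entry.intensity]
        fb = self.category_fallback.get(entry.category)
        if fb is None or entry.intensity not in fb:
            raise ScoringError(
                f"no MET value for activity {entry.activity!r} "
                f"(category {entry.category!r}, intensity {entry.intensity!r})"
            )
        return fb[entry.intensity]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MetTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            activities=raw.get("activities", {}),
            category_fallback=raw["category_fallback"],
        )


def met_intensity_band(met: float) -> str:
    """Band for a MET value: [0,2) sedentary, [2,4) light, [4,6.5) moderate, [6.5,inf) vigorous."""
    if met <= 0:
        raise ValueError("MET value must be positive")
    if met < 2.0:
        return "sedentary"
    if met < 4.0:
        return "light"
    if met < 6.5:
        return "moderate"
    return "vigorous"


def score_aquaa(resp: AquaaResponse, mets: MetTable) -> AquaaScores:
    """Score an AQuAA response into the five weekly outcomes."""
    band_min = {"sedentary": 0.0, "light": 0.0, "moderate": 0.0, "vigorous": 0.0}
    total = 0.0
    for entry in resp.entries:
        met = mets.lookup(entry)
        minutes = entry.weekly_minutes
        band_min[met_intensity_band(met)] += minutes
        if met >= 2.0:
            total += met * minutes
    return AquaaScores(
        total_score=total,
        sedentary_min=band_min["sedentary"],
        light_min=band_min["light"],
        moderate_min=band_min["moderate"],
        vigorous_min=band_min["vigorous"],
    )


# ---------------------------------------------------------------------------
# PASE


@dataclass
class PaseItem:
    item: str
    frequency: str
    duration: Optional[str] = None

    def __post_init__(self) -> None:
        if self.frequency not in PASE_FREQUENCIES:
            raise ValueError(f"unknown PASE frequency: {self.frequency!r}")
        if self.frequency != "never" and self.duration not in PASE_DURATIONS:
            raise ValueError(f"unknown PASE duration: {self.duration!r}")


@dataclass
class PaseWork:
    worked: bool = False
    sitting_only: bool = False
    hours: Optional[str] = None

    def __post_init__(self) -> None:
        if self.worked and self.hours not in PASE_WORK_HOURS:
            raise ValueError(f"unknown PASE work hours category: {self.hours!r}")


@dataclass
class PaseResponse:
    subject: str
    visit: str
    items: list[PaseItem] = field(default_factory=list)
    work: PaseWork = field(default_factory=PaseWork)

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "visit": self.visit,
            "items": [
                {"item": i.item, "frequency": i.frequency, "duration": i.duration}
                for i in self.items
            ],
            "work": {
                "worked": self.work.worked,
                "sitting_only": self.work.sitting_only,
                "hours": self.work.hours,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PaseResponse":
        return cls(
            subject=d["subject"],
            visit=d["visit"],
            items=[PaseItem(**i) for i in d.get("items", [])],
            work=PaseWork(**d.get("work", {})),
        )


@dataclass
class PaseWeights:
    """External PASE item weights plus ordinal-category midpoint maps."""

    weights: dict[str, float]
    frequency_days: dict[str, float]
    duration_hours: dict[str, float]
    work_hours_per_week: dict[str, float]
    sedentary_items: frozenset[str] = frozenset({"sitting"})

    def __post_init__(self) -> None:
        self.sedentary_items = frozenset(self.sedentary_items)
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("PASE weights must be non-negative")
        for maps, order in (
            (self.frequency_days, PASE_FREQUENCIES),
            (self.duration_hours, PASE_DURATIONS),
            (self.work_hours_per_week, PASE_WORK_HOURS),
        ):
            vals = [maps[c] for c in order]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError("midpoint maps must be monotone increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PaseWeights":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            weights={k: float(v) for k, v in raw["weights"].items()},
            frequency_days=raw["frequency_days"],
            duration_hours=raw["duration_hours"],
            work_hours_per_week=raw["work_hours_per_week"],
            sedentary_items=frozenset(raw.get("sedentary_items", ["sitting"])),
        )


@dataclass
class PaseScores:
    sum_score: float
    total_pa_min: float  # weekly minutes of non-sedentary activity
    sedentary_min: float  # weekly minutes of sitting items / sitting-only work


def pase_hours_per_week(
    frequency: str, duration: Optional[str], maps: PaseWeights
) -> float:
    """Hours/week from ordinal answers: days/week midpoint x hours/day midpoint."""
    if frequency not in PASE_FREQUENCIES:
        raise ValueError(f"unknown PASE frequency: {frequency!r}")
    if frequency == "never":
        return 0.0
    if duration not in PASE_DURATIONS:
        raise ValueError(f"unknown PASE duration: {duration!r}")
    return maps.frequency_days[frequency] * maps.duration_hours[duration]


def score_pase(resp: PaseResponse, weights: PaseWeights) -> PaseScores:
    """Weighted PASE sum score plus weekly activity and sedentary minutes.

    ``sum_score = sum_j weight_j * hours_per_week_j`` over weighted items;
    sitting items and sitting-only work accrue sedentary minutes only.
    """
    if weights is None:
        raise ScoringError("PASE scoring requires an item-weights configuration")
    sum_score = 0.0
    active_h = 0.0
    sedentary_h = 0.0
    for item in resp.items:
        hours = pase_hours_per_week(item.frequency, item.duration, weights)
        if item.item in weights.sedentary_items:
            sedentary_h += hours
            continue
        if item.item not in weights.weights:
            raise ScoringError(f"no PASE weight for item {item.item!r}")
        sum_score += weights.weights[item.item] * hours
        active_h += hours
    if resp.work.worked:
        hours = weights.work_hours_per_week[resp.work.hours]
        if resp.work.sitting_only:
            sedentary_h += hours
        else:
            if "work" not in weights.weights:
                raise ScoringError("no PASE weight for item 'work'")
            sum_score += weights.weights["work"] * hours
            active_h += hours
    return PaseScores(
        sum_score=sum_score,
        total_pa_min=60.0 * active_h,
        sedentary_min=60.0 * sedentary_h,
    )


# ---------------------------------------------------------------------------
# Shipped default configurations


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pametrics").joinpath("data", name)))


def default_met_table() -> MetTable:
    """Editable compendium-style defaults shipped with the package."""
    return MetTable.from_yaml(_data_path("met_table.yaml"))


def default_pase_weights() -> PaseWeights:
    """Published PASE item weights (external source) shipped as configuration."""
    return PaseWeights.from_yaml(_data_path("pase_weights.yaml"))
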