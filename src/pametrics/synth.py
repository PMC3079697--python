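"""Synthetic cohorts with known ground truth for the full pipeline.

The generator emulates a small oncology cohort (default n = 50) measured
twice with two activity questionnaires five days apart and wearing a hip
accelerometer for seven days:

* **Paired scores.**  Each score follows a one-way random-effects model:
  a subject's true score is drawn from a right-skewed between-subject
  distribution and each administration adds independent normal error.  The
  population ICC is ``between_var / (between_var + error_var)`` and can be
  set directly.  The skewed latent family is a Gamma distribution fitted to
  a target interquartile range: weekly activity minutes are bounded and
  right-skewed, which a Gamma captures without the unrealistically heavy
  upper tail a lognormal fitted to the same quartiles would imply.

* **Questionnaire responses.**  Rather than emitting numeric scores, the
  generator *inverts* the scoring maps: it builds AQuAA entries (fixed
  marker activities with known METs, 7 days/week, rounded minutes/day) and
  PASE category answers (greedy largest-fit over the ordinal grid) that
  score back to the simulated target, so questionnaire scoring is exercised
  end-to-end.  AQuAA targets round-trip to within half a day-minute
  (<= 3.5 min/week per band); PASE targets to within the smallest item
  increment of the ordinal grid.

* **Epoch streams.**  Each day has a sleep gap and an evening gap of zero
  counts around a contiguous wear window (default 810 min/day).  Wear
  minutes draw an intensity band from a mixture whose active-band weights
  scale with the subject's activity level, then a counts/min value from a
  band-specific distribution; minutes are split multinomially into four
  15-s epochs.  Additional non-wear blocks can be planted exactly.

* **Construct correlation.**  A Gaussian copula links the questionnaire
  latent to the accelerometer activity level so the cohort-level Spearman
  correlation between scores and counts/min approximates ``rho_construct``
  (the Pearson correlation of the copula is ``2 sin(pi rho / 6)``).

All randomness derives from a single seed through named
``numpy.random.SeedSequence`` substreams, with one substream per subject
for the epoch data, so cohorts are bit-reproducible and a subject's stream
does not depend on how many other subjects are simulated after it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .accel import EpochSeries, write_epoch_csv
from .questionnaires import (
    AquaaEntry,
    AquaaResponse,
    PaseItem,
    PaseResponse,
    PaseWeights,
    PaseWork,
    default_pase_weights,
)
from .reliability import PairedScores

__all__ = [
    "ScoreModel",
    "NonwearBlock",
    "EpochSettings",
    "SimulationConfig",
    "SyntheticSubject",
    "SyntheticCohort",
    "default_score_models",
    "simulate_paired_scores",
    "simulate_score_pairs",
    "simulate_epoch_stream",
    "simulate_cohort",
    "invert_aquaa",
    "invert_pase",
    "write_cohort",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


# ---------------------------------------------------------------------------
# Score models


@dataclass
class ScoreModel:
    """Latent-score distribution and error model for one paired score.

    ``dist="normal"`` uses ``mean``/``between_sd`` directly;
    ``dist="gamma"`` fits a Gamma to the quartile pair (``q25``, ``q75``).
    The within-subject error SD is either given (``error_sd``) or derived
    from a target population ``icc``.  ``invert=True`` makes the score
    decrease with the shared activity latent (sedentary outcomes).
    """

    name: str
    dist: str = "normal"
    mean: float = 0.0
    between_sd: float = 1.0
    q25: float = math.nan
    q75: float = math.nan
    error_sd: Optional[float] = None
    icc: Optional[float] = None
    invert: bool = False
    units: str = ""

    def __post_init__(self) -> None:
        if self.dist not in ("normal", "gamma"):
            raise ConfigurationError(f"{self.name}: unknown dist {self.dist!r}")
        if self.dist == "normal" and self.between_sd < 0:
            raise ConfigurationError(f"{self.name}: between_sd must be >= 0")
        if self.dist == "gamma" and not 0 < self.q25 < self.q75:
            raise ConfigurationError(f"{self.name}: need 0 < q25 < q75")
        if self.error_sd is None and self.icc is None:
            raise ConfigurationError(f"{self.name}: set error_sd or icc")
        if self.error_sd is not None and self.error_sd < 0:
            raise ConfigurationError(f"{self.name}: error_sd must be >= 0")
        if self.icc is not None and not -1.0 <= self.icc <= 1.0:
            raise ConfigurationError(f"{self.name}: icc must be in [-1, 1]")
        self._gamma_shape: Optional[float] = None
        self._gamma_scale: Optional[float] = None
        if self.dist == "gamma":
            self._gamma_shape, self._gamma_scale = _fit_gamma_quartiles(
                self.q25, self.q75
            )

    @property
    def between_var(self) -> float:
        if self.dist == "normal":
            return self.between_sd**2
        assert self._gamma_shape is not None and self._gamma_scale is not None
        return self._gamma_shape * self._gamma_scale**2

    @property
    def error_sd_value(self) -> float:
        if self.error_sd is not None:
            return self.error_sd
        icc = max(float(self.icc), 1e-12)  # type: ignore[arg-type]
        if icc >= 1.0:
            return 0.0
        return math.sqrt(self.between_var * (1.0 - icc) / icc)

    @property
    def population_icc(self) -> float:
        bv = self.between_var
        ev = self.error_sd_value**2
        if bv + ev == 0.0:
            return math.nan
        return bv / (bv + ev)

    def latent(self, z: np.ndarray) -> np.ndarray:
        """Latent true scores via quantile transform of standard-normal z."""
        z = np.asarray(z, dtype=float)
        zz = -z if self.invert else z
        if self.dist == "normal":
            return self.mean + self.between_sd * zz
        u = stats.norm.cdf(zz)
        return stats.gamma.ppf(u, self._gamma_shape, scale=self._gamma_scale)


def _fit_gamma_quartiles(q25: float, q75: float) -> tuple[float, float]:
    """Gamma (shape, scale) whose 25th/75th percentiles match the targets."""
    ratio = q75 / q25

    def gap(log_shape: float) -> float:
        k = math.exp(log_shape)
        return stats.gamma.ppf(0.75, k) / stats.gamma.ppf(0.25, k) - ratio

    log_shape = optimize.brentq(gap, -6.0, 10.0)
    shape = math.exp(log_shape)
    scale = q25 / stats.gamma.ppf(0.25, shape)
    return shape, scale


def default_score_models() -> dict[str, ScoreModel]:
    """Primitive score models calibrated to a typical mixed-cancer cohort.

    Quartiles and reliabilities reflect published values for these
    instruments in cancer patients; the remaining pipeline outcomes (AQuAA
    total score/total minutes, PASE total minutes) are derived from these
    primitives when responses are scored.
    """
    return {
        "aquaa_light": ScoreModel(
            "aquaa_light", dist="gamma", q25=660, q75=1853, icc=0.57, units="min/wk"
        ),
        "aquaa_mvpa": ScoreModel(
            "aquaa_mvpa", dist="gamma", q25=34, q75=450, icc=0.70, units="min/wk"
        ),
        "aquaa_sedentary": ScoreModel(
            "aquaa_sedentary",
            dist="gamma",
            q25=2078,
            q75=3720,
            icc=0.78,
            invert=True,
            units="min/wk",
        ),
        "pase_sum": ScoreModel(
            "pase_sum", dist="gamma", q25=49, q75=161, icc=0.89, units="PASE"
        ),
        "pase_sedentary": ScoreModel(
            "pase_sedentary",
            dist="gamma",
            q25=542,
            q75=1802,
            icc=0.67,
            invert=True,
            units="min/wk",
        ),
    }


# ---------------------------------------------------------------------------
# Epoch settings


@dataclass(frozen=True)
class NonwearBlock:
    day: int
    start_minute: int
    duration_minutes: int

    def __post_init__(self) -> None:
        if self.duration_minutes < 0:
            raise ConfigurationError("nonwear_blocks: duration must be >= 0")
        if not 0 <= self.start_minute < 1440:
            raise ConfigurationError("nonwear_blocks: start_minute outside day")
        if self.start_minute + self.duration_minutes > 1440:
            raise ConfigurationError("nonwear_blocks: block must fit inside a day")


@dataclass
class EpochSettings:
    """Geometry and count distributions of the simulated accelerometer week.

    Wear minutes draw a band from ``band_base_weights`` (sedentary, light,
    moderate, vigorous) with the light weight scaled by
    ``exp(light_effect * z)`` and the moderate/vigorous weights by
    ``exp(mvpa_effect * z)`` for a subject with activity latent ``z``.
    Band-conditional counts/min: sedentary is zero with probability
    ``sed_zero_prob`` else uniform below the light cut-point; light and
    moderate are cut-point offsets plus a truncated Gamma; vigorous is the
    cut-point plus an exponential tail.
    """

    days: int = 7
    epoch_seconds: int = 15
    wear_start_minute: int = 450  # 07:30, after the overnight gap
    wear_minutes_per_day: int = 810
    nonwear_blocks: tuple[NonwearBlock, ...] = ()
    band_base_weights: tuple[float, float, float, float] = (0.763, 0.198, 0.037, 0.002)
    light_effect: float = 0.35
    mvpa_effect: float = 0.65
    sed_zero_prob: float = 0.35
    light_gamma: tuple[float, float] = (1.5, 400.0)
    moderate_gamma: tuple[float, float] = (1.5, 700.0)
    vigorous_exp_mean: float = 600.0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ConfigurationError("days must be >= 1")
        if self.epoch_seconds != 15:
            raise ConfigurationError("epoch_seconds must be 15")
        if not 0 <= self.wear_minutes_per_day <= 1440:
            raise ConfigurationError("wear_minutes_per_day must be in [0, 1440]")
        if self.wear_start_minute + self.wear_minutes_per_day > 1440:
            raise ConfigurationError("wear window must fit inside a day")
        if any(w < 0 for w in self.band_base_weights) or sum(
            self.band_base_weights
        ) <= 0:
            raise ConfigurationError("band_base_weights must be non-negative")
        blocks = sorted(
            (b for b in self.nonwear_blocks), key=lambda b: (b.day, b.start_minute)
        )
        for a, b in zip(blocks, blocks[1:]):
            if a.day == b.day and a.start_minute + a.duration_minutes > b.start_minute:
                raise ConfigurationError("nonwear_blocks overlap")
        for b in blocks:
            if not 0 <= b.day < self.days:
                raise ConfigurationError("nonwear_blocks: day outside range")


# ---------------------------------------------------------------------------
# Simulation config and cohort containers


@dataclass
class SimulationConfig:
    n_subjects: int = 50
    seed: int = 0
    scores: dict[str, ScoreModel] = field(default_factory=default_score_models)
    epochs: EpochSettings = field(default_factory=EpochSettings)
    rho_construct: float = 0.10
    moderate_fraction_of_mvpa: float = 0.85

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not -1.0 <= self.rho_construct <= 1.0:
            raise ConfigurationError("rho_construct must be in [-1, 1]")
        if not 0.0 <= self.moderate_fraction_of_mvpa <= 1.0:
            raise ConfigurationError("moderate_fraction_of_mvpa must be in [0, 1]")


@dataclass
class SyntheticSubject:
    subject: str
    aquaa_t0: AquaaResponse
    aquaa_t1: AquaaResponse
    pase_t0: PaseResponse
    pase_t1: PaseResponse
    epochs: EpochSeries
    truth: dict


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    subjects: list[SyntheticSubject]
    paired_scores: dict[str, PairedScores]

    @property
    def ground_truth(self) -> pd.DataFrame:
        return pd.DataFrame([s.truth for s in self.subjects])


# ---------------------------------------------------------------------------
# Paired-score simulation


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1, index]))


def simulate_score_pairs(
    model: ScoreModel,
    n: int,
    rng: np.random.Generator,
    z: Optional[np.ndarray] = None,
    floor_zero: bool = False,
) -> PairedScores:
    """Draw n paired (T0, T1) observations from one score model."""
    if z is None:
        z = rng.standard_normal(n)
    latent = model.latent(z)
    esd = model.error_sd_value
    t0 = latent + rng.normal(0.0, esd, n) if esd > 0 else latent.copy()
    t1 = latent + rng.normal(0.0, esd, n) if esd > 0 else latent.copy()
    if floor_zero:
        t0 = np.maximum(t0, 0.0)
        t1 = np.maximum(t1, 0.0)
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    return PairedScores(model.name, subjects, t0, t1, model.units)


def _draw_subject(
    cfg: SimulationConfig, index: int
) -> tuple[float, float, dict[str, tuple[float, float]], np.random.Generator]:
    """All latent/score draws for one subject from its own substream.

    Returns (z_activity, z_counts, {score: (t0, t1)}, rng) with the rng
    positioned for subsequent epoch-stream generation, so a subject's data
    do not depend on how many other subjects are simulated.
    """
    rng = _subject_rng(cfg.seed, index)
    z_pa, eps = rng.standard_normal(2)
    r_pearson = 2.0 * math.sin(math.pi * cfg.rho_construct / 6.0)
    z_cpm = r_pearson * z_pa + math.sqrt(1.0 - r_pearson**2) * eps
    draws: dict[str, tuple[float, float]] = {}
    for name, model in cfg.scores.items():
        latent = float(model.latent(np.array([z_pa]))[0])
        esd = model.error_sd_value
        e0, e1 = rng.normal(0.0, esd, 2) if esd > 0 else (0.0, 0.0)
        draws[name] = (max(latent + e0, 0.0), max(latent + e1, 0.0))
    return float(z_pa), float(z_cpm), draws, rng


def simulate_paired_scores(cfg: SimulationConfig) -> list[PairedScores]:
    """Paired scores for every configured score, sharing the activity latent.

    Identical to the scores embedded in :func:`simulate_cohort` for the
    same configuration (observed values are floored at zero, as no
    questionnaire response can encode a negative score).
    """
    per_subject = [_draw_subject(cfg, i) for i in range(cfg.n_subjects)]
    subjects = [f"S{i + 1:03d}" for i in range(cfg.n_subjects)]
    out = []
    for name, model in cfg.scores.items():
        t0 = np.array([d[2][name][0] for d in per_subject])
        t1 = np.array([d[2][name][1] for d in per_subject])
        out.append(PairedScores(name, subjects, t0, t1, model.units))
    return out


# ---------------------------------------------------------------------------
# Epoch-stream simulation


def _split_to_epochs(
    minute_counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Split integer minute counts into 4 epochs (multinomial, p = 1/4 each)."""
    remaining = minute_counts.astype(np.int64)
    epochs = np.empty((minute_counts.size, 4), dtype=np.int64)
    for j in range(3):
        draw = rng.binomial(remaining, 1.0 / (4 - j))
        epochs[:, j] = draw
        remaining = remaining - draw
    epochs[:, 3] = remaining
    return epochs.reshape(-1)


def simulate_epoch_stream(
    settings: EpochSettings,
    activity_z: float,
    rng: np.random.Generator,
    subject: str = "S001",
    start: str | pd.Timestamp = "2010-01-04 00:00:00",
) -> tuple[EpochSeries, float]:
    """Simulate one subject's epoch stream; returns (series, wear-mean counts/min).

    The returned counts/min is the realized wear-time mean computed from the
    generated minute counts (planted non-wear excluded), recorded as ground
    truth at generation time.
    """
    n_min_day = 1440
    total_min = settings.days * n_min_day
    minute_counts = np.zeros(total_min, dtype=np.int64)
    wear_mask = np.zeros(total_min, dtype=bool)
    for d in range(settings.days):
        lo = d * n_min_day + settings.wear_start_minute
        wear_mask[lo : lo + settings.wear_minutes_per_day] = True
    for b in settings.nonwear_blocks:
        lo = b.day * n_min_day + b.start_minute
        wear_mask[lo : lo + b.duration_minutes] = False

    n_wear = int(wear_mask.sum())
    if n_wear:
        w = np.array(settings.band_base_weights, dtype=float)
        w[1] *= math.exp(settings.light_effect * activity_z)
        w[2:] *= math.exp(settings.mvpa_effect * activity_z)
        w /= w.sum()
        band = rng.choice(4, size=n_wear, p=w)
        cpm = np.zeros(n_wear)
        sed = band == 0
        n_sed = int(sed.sum())
        sed_vals = rng.uniform(0.0, 100.0, n_sed)
        sed_vals[rng.random(n_sed) < settings.sed_zero_prob] = 0.0
        cpm[sed] = sed_vals
        li = band == 1
        k, s = settings.light_gamma
        cpm[li] = 100.0 + np.minimum(rng.gamma(k, s, int(li.sum())), 1851.0)
        mo = band == 2
        k, s = settings.moderate_gamma
        cpm[mo] = 1952.0 + np.minimum(rng.gamma(k, s, int(mo.sum())), 3772.0)
        vi = band == 3
        cpm[vi] = 5725.0 + rng.exponential(settings.vigorous_exp_mean, int(vi.sum()))
        minute_counts[wear_mask] = np.rint(cpm).astype(np.int64)
        realized_cpm = float(minute_counts[wear_mask].sum() / n_wear)
    else:
        realized_cpm = float("nan")

    epochs = _split_to_epochs(minute_counts, rng)
    series = EpochSeries(
        subject=subject, start=pd.Timestamp(start), counts=epochs,
        epoch_seconds=settings.epoch_seconds,
    )
    return series, realized_cpm


# ---------------------------------------------------------------------------
# Response inversion

#: Marker activities used when inverting AQuAA band-minute targets; the MET
#: values match the shipped default MET table exactly.
AQUAA_MARKERS = {
    "sedentary": ("leisure", "television", "low", 1.0),
    "light": ("leisure", "walking", "medium", 3.0),
    "moderate": ("sports", "cycling", "medium", 5.0),
    "vigorous": ("sports", "jogging", "high", 7.5),
}


def invert_aquaa(
    band_minutes: dict[str, float], subject: str, visit: str
) -> AquaaResponse:
    """AQuAA entries that score back to the target weekly band minutes.

    One marker entry per non-zero band, 7 days/week with minutes/day rounded
    to the nearest integer, so each band round-trips to within 3.5 min/week.
    """
    entries = []
    for band, target in band_minutes.items():
        category, activity, intensity, _ = AQUAA_MARKERS[band]
        per_day = int(round(max(target, 0.0) / 7.0))
        if per_day <= 0:
            continue
        entries.append(
            AquaaEntry(
                category=category,
                activity=activity,
                days_per_week=7,
                minutes_per_day=per_day,
                intensity=intensity,
            )
        )
    return AquaaResponse(subject=subject, visit=visit, entries=entries)


def invert_pase(
    sum_target: float,
    sedentary_minutes: float,
    subject: str,
    visit: str,
    weights: Optional[PaseWeights] = None,
) -> PaseResponse:
    """PASE category answers approximating a target sum score.

    Greedy largest-fit: items are visited in descending weight order and
    each takes the (frequency, duration) combination with the largest
    contribution not exceeding the remaining target, leaving a residual
    below the smallest non-zero item increment of the ordinal grid.  The
    sitting item takes the combination closest to the sedentary target.
    """
    weights = weights or default_pase_weights()
    freq_opts = [(f, d) for f in ("seldom", "sometimes", "often")
                 for d in ("lt1h", "h1to2", "h2to4", "gt4h")]

    def hours(f: str, d: str) -> float:
        return weights.frequency_days[f] * weights.duration_hours[d]

    items: list[PaseItem] = []
    remaining = max(sum_target, 0.0)
    order = sorted(
        (k for k in weights.weights if k != "work"),
        key=lambda k: -weights.weights[k],
    )
    for item_id in order:
        w = weights.weights[item_id]
        best = None
        best_val = 0.0
        for f, d in freq_opts:
            val = w * hours(f, d)
            if val <= remaining + 1e-9 and val > best_val:
                best, best_val = (f, d), val
        if best is not None:
            items.append(PaseItem(item=item_id, frequency=best[0], duration=best[1]))
            remaining -= best_val
    sed_target_h = max(sedentary_minutes, 0.0) / 60.0
    best_sit = min(
        [("never", None, 0.0)] + [(f, d, hours(f, d)) for f, d in freq_opts],
        key=lambda t: abs(t[2] - sed_target_h),
    )
    items.append(PaseItem(item="sitting", frequency=best_sit[0], duration=best_sit[1]))
    return PaseResponse(
        subject=subject, visit=visit, items=items, work=PaseWork(worked=False)
    )


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_cohort(
    cfg: SimulationConfig, weights: Optional[PaseWeights] = None
) -> SyntheticCohort:
    """Full synthetic cohort: responses at T0/T1 plus epoch streams.

    The observed (noisy) targets for each subject-visit are floored at zero
    before response inversion, since no response can encode a negative
    score; ground truth records the encoded targets exactly as simulated.
    """
    weights = weights or default_pase_weights()
    n = cfg.n_subjects

    subjects: list[SyntheticSubject] = []
    mf = cfg.moderate_fraction_of_mvpa
    all_draws = []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        z_pa, z_cpm, draws, ep_rng = _draw_subject(cfg, i)
        all_draws.append(draws)
        responses: dict[str, tuple[AquaaResponse, PaseResponse]] = {}
        for visit in ("T0", "T1"):
            get = lambda nm: draws[nm][0 if visit == "T0" else 1]
            mvpa = get("aquaa_mvpa")
            band_targets = {
                "sedentary": get("aquaa_sedentary"),
                "light": get("aquaa_light"),
                "moderate": mf * mvpa,
                "vigorous": (1.0 - mf) * mvpa,
            }
            aquaa = invert_aquaa(band_targets, sid, visit)
            pase = invert_pase(
                get("pase_sum"), get("pase_sedentary"), sid, visit, weights
            )
            responses[visit] = (aquaa, pase)
        series, realized_cpm = simulate_epoch_stream(
            cfg.epochs, z_cpm, ep_rng, subject=sid
        )
        truth = {
            "subject": sid,
            "z_activity": z_pa,
            "z_counts": z_cpm,
            "realized_counts_per_min": realized_cpm,
        }
        for name in cfg.scores:
            truth[f"{name}_t0"] = draws[name][0]
            truth[f"{name}_t1"] = draws[name][1]
        subjects.append(
            SyntheticSubject(
                subject=sid,
                aquaa_t0=responses["T0"][0],
                aquaa_t1=responses["T1"][0],
                pase_t0=responses["T0"][1],
                pase_t1=responses["T1"][1],
                epochs=series,
                truth=truth,
            )
        )
    sids = [s.subject for s in subjects]
    paired = {
        name: PairedScores(
            name,
            sids,
            np.array([d[name][0] for d in all_draws]),
            np.array([d[name][1] for d in all_draws]),
            model.units,
        )
        for name, model in cfg.scores.items()
    }
    return SyntheticCohort(config=cfg, subjects=subjects, paired_scores=paired)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort to disk: epoch CSVs, response JSONs, ground-truth CSV."""
    outdir = Path(outdir)
    (outdir / "epochs").mkdir(parents=True, exist_ok=True)
    (outdir / "responses").mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        write_epoch_csv(s.epochs, outdir / "epochs" / f"{s.subject}.csv")
        for visit, aquaa, pase in (
            ("T0", s.aquaa_t0, s.pase_t0),
            ("T1", s.aquaa_t1, s.pase_t1),
        ):
            payload = {
                "subject": s.subject,
                "visit": visit,
                "aquaa": aquaa.to_dict(),
                "pase": pase.to_dict(),
            }
            path = outdir / "responses" / f"{s.subject}_{visit}.json"
            path.write_text(json.dumps(payload, indent=1))
    cohort.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
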