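"""Pipeline orchestration: cohort -> scores -> summaries -> result tables.

``run_pipeline`` drives the full analysis either from a synthetic cohort
(generated in-process with a recorded seed) or from files on disk
(questionnaire response JSONs plus epoch CSVs).  It writes:

* ``scores.csv`` — long table (subject, visit, score, value),
* ``accel_summaries.csv`` — one row per subject with wear/validity flags,
* ``reliability_table.csv`` — the test-retest table (medians, ICC with
  95% CI, SEM, SDD95, SDD95/range95 ratio, steps, rating),
* ``validity_table.csv`` — questionnaire-vs-accelerometer correlations and
  agreement ICCs over included subjects,
* ``manifest.json`` — seed, config hash, library versions, row counts and
  every excluded subject with the reason, so runs are replayable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .accel import (
    CutPoints,
    EpochSeries,
    apply_journal_mask,
    detect_nonwear,
    read_epoch_csv,
    read_journal_csv,
    summaries_to_frame,
    summarize_subject,
    to_minutes,
)
from .questionnaires import (
    AquaaResponse,
    MetTable,
    PaseResponse,
    PaseWeights,
    default_met_table,
    default_pase_weights,
    score_aquaa,
    score_pase,
)
from .reliability import reliability_table
from .synth import SimulationConfig, simulate_cohort, write_cohort
from .validity import acsm_compliance, validity_table

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "score_responses",
    "process_epoch_series",
    "SCORE_NAMES",
    "VALIDITY_CORRELATE",
    "VALIDITY_AGREE",
]

SCORE_NAMES = (
    "aquaa_score",
    "aquaa_total_pa",
    "aquaa_light",
    "aquaa_mvpa",
    "aquaa_sedentary",
    "pase_sum",
    "pase_total_pa",
    "pase_sedentary",
)

VALIDITY_CORRELATE = (
    ("aquaa_score", "counts_per_min"),
    ("pase_sum", "counts_per_min"),
)

VALIDITY_AGREE = (
    ("aquaa_total_pa", "total_pa_min_per_wk"),
    ("aquaa_light", "light_min_per_wk"),
    ("aquaa_mvpa", "mvpa_min_per_wk"),
    ("aquaa_sedentary", "sedentary_min_per_wk"),
    ("pase_total_pa", "total_pa_min_per_wk"),
    ("pase_sedentary", "sedentary_min_per_wk"),
)


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    outdir: str = "out"
    seed: int = 0
    n_subjects: int = 50
    responses_dir: Optional[str] = None
    epochs_dir: Optional[str] = None
    journal: Optional[str] = None
    met_table: Optional[str] = None
    pase_weights: Optional[str] = None
    cutpoints: Optional[str] = None
    write_raw_cohort: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown pipeline mode: {self.mode!r}")
        if self.mode == "files":
            for name in ("responses_dir", "epochs_dir"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{name} missing or does not exist: {path}")
        for name in ("met_table", "pase_weights", "cutpoints", "journal"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def score_responses(
    responses: list[tuple[AquaaResponse, PaseResponse]],
    mets: MetTable,
    weights: PaseWeights,
) -> pd.DataFrame:
    """Score paired AQuAA/PASE responses into the long scores frame."""
    rows = []
    for aquaa, pase in responses:
        a = score_aquaa(aquaa, mets)
        p = score_pase(pase, weights)
        values = {
            "aquaa_score": a.total_score,
            "aquaa_total_pa": a.total_pa_min,
            "aquaa_light": a.light_min,
            "aquaa_mvpa": a.mvpa_min,
            "aquaa_sedentary": a.sedentary_min,
            "pase_sum": p.sum_score,
            "pase_total_pa": p.total_pa_min,
            "pase_sedentary": p.sedentary_min,
        }
        for score, value in values.items():
            rows.append(
                {
                    "subject": aquaa.subject,
                    "visit": aquaa.visit,
                    "score": score,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def process_epoch_series(
    series: list[EpochSeries],
    cutpoints: CutPoints = CutPoints(),
    journal: Optional[dict] = None,
) -> pd.DataFrame:
    """Epoch streams -> per-subject weekly summaries (with wear detection)."""
    summaries = []
    for s in series:
        m = detect_nonwear(to_minutes(s))
        if journal and s.subject in journal:
            m = apply_journal_mask(m, journal[s.subject])
        summaries.append(summarize_subject(m, cutpoints))
    return summaries_to_frame(summaries)


def _load_file_inputs(
    cfg: PipelineConfig,
) -> tuple[list[tuple[AquaaResponse, PaseResponse]], list[EpochSeries]]:
    responses = []
    for path in sorted(Path(cfg.responses_dir).glob("*.json")):
        payload = json.loads(path.read_text())
        responses.append(
            (
                AquaaResponse.from_dict(payload["aquaa"]),
                PaseResponse.from_dict(payload["pase"]),
            )
        )
    series = [
        read_epoch_csv(path) for path in sorted(Path(cfg.epochs_dir).glob("*.csv"))
    ]
    return responses, series


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the output manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mets = MetTable.from_yaml(cfg.met_table) if cfg.met_table else default_met_table()
    weights = (
        PaseWeights.from_yaml(cfg.pase_weights)
        if cfg.pase_weights
        else default_pase_weights()
    )
    cutpoints = CutPoints.from_yaml(cfg.cutpoints) if cfg.cutpoints else CutPoints()
    journal = read_journal_csv(cfg.journal) if cfg.journal else None

    if cfg.mode == "synthetic":
        sim = SimulationConfig(n_subjects=cfg.n_subjects, seed=cfg.seed)
        cohort = simulate_cohort(sim, weights=weights)
        if cfg.write_raw_cohort:
            write_cohort(cohort, outdir / "cohort")
        responses = [(s.aquaa_t0, s.pase_t0) for s in cohort.subjects] + [
            (s.aquaa_t1, s.pase_t1) for s in cohort.subjects
        ]
        series = [s.epochs for s in cohort.subjects]
    else:
        responses, series = _load_file_inputs(cfg)

    scores = score_responses(responses, mets, weights)
    accel = process_epoch_series(series, cutpoints, journal)

    rel_table = reliability_table(scores, SCORE_NAMES)

    exclusions = [
        {"subject": str(r.subject), "reason": "fewer than 5 valid wearing days"}
        for r in accel.itertuples()
        if not r.included
    ]
    n_included = int(accel["included"].sum()) if len(accel) else 0
    if n_included >= 2:
        val_table = validity_table(
            scores, accel, correlate=VALIDITY_CORRELATE, agree=VALIDITY_AGREE
        )
        noncompliant = acsm_compliance(
            accel.loc[accel["included"], "mvpa_min_per_wk"].to_numpy()
        )
    else:
        warnings.warn("no included accelerometer subjects: validity table empty")
        val_table = pd.DataFrame(
            columns=[
                "score", "accel_measure", "statistic", "n", "value",
                "p_value", "ci_low", "ci_high", "adequate",
            ]
        )
        noncompliant = None

    scores.to_csv(outdir / "scores.csv", index=False)
    accel.to_csv(outdir / "accel_summaries.csv", index=False)
    rel_table.to_csv(outdir / "reliability_table.csv", index=False)
    val_table.to_csv(outdir / "validity_table.csv", index=False)

    cfg_dict = {k: getattr(cfg, k) for k in vars(cfg)}
    manifest = {
        "pametrics_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_subjects_scored": int(scores["subject"].nunique()),
        "n_accel_subjects": int(len(accel)),
        "n_accel_included": n_included,
        "exclusions": exclusions,
        "acsm_noncompliant_fraction": noncompliant,
        "rows": {
            "scores": int(len(scores)),
            "reliability_table": int(len(rel_table)),
            "validity_table": int(len(val_table)),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
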