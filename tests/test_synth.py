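"""Synthetic-cohort generator: determinism, parameter recovery, inversion."""

import numpy as np
import pytest
from scipy import stats

from pametrics.accel import detect_nonwear, summarize_subject, to_minutes
from pametrics.questionnaires import score_aquaa, score_pase
from pametrics.reliability import icc_oneway, variance_components
from pametrics.synth import (
    AQUAA_MARKERS,
    ConfigurationError,
    EpochSettings,
    NonwearBlock,
    ScoreModel,
    SimulationConfig,
    SyntheticCohort,
    invert_aquaa,
    invert_pase,
    simulate_cohort,
    simulate_epoch_stream,
    simulate_paired_scores,
    simulate_score_pairs,
)


def small_config(**kwargs):
    defaults = dict(n_subjects=6, seed=11)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestScoreModel:
    def test_zero_error_gives_identical_visits(self, rng):
        m = ScoreModel("x", dist="normal", mean=5, between_sd=2, error_sd=0.0)
        p = simulate_score_pairs(m, 50, rng)
        assert np.array_equal(p.t0, p.t1)
        assert m.population_icc == 1.0

    def test_zero_between_gives_population_icc_zero(self, rng):
        m = ScoreModel("x", dist="normal", mean=5, between_sd=0.0, error_sd=1.0)
        # every subject shares the same latent; only error remains
        assert np.unique(m.latent(rng.standard_normal(20))).size == 1
        assert m.population_icc == 0.0

    def test_icc_recovered_at_large_n(self, rng):
        m = ScoreModel(
            "x", dist="normal", mean=0, between_sd=np.sqrt(7), error_sd=np.sqrt(3)
        )
        p = simulate_score_pairs(m, 2000, rng)
        icc, _ = icc_oneway(variance_components(p))
        assert icc == pytest.approx(0.70, abs=0.03)

    def test_gamma_latent_matches_target_quartiles(self, rng):
        m = ScoreModel("x", dist="gamma", q25=660, q75=1853, error_sd=0.0)
        lat = m.latent(rng.standard_normal(200_000))
        q25, q75 = np.percentile(lat, [25, 75])
        assert q25 == pytest.approx(660, rel=0.02)
        assert q75 == pytest.approx(1853, rel=0.02)

    def test_error_sd_derived_from_target_icc(self):
        m = ScoreModel("x", dist="gamma", q25=100, q75=300, icc=0.7)
        assert m.population_icc == pytest.approx(0.7)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="between_sd"):
            ScoreModel("x", dist="normal", between_sd=-1, error_sd=1)
        with pytest.raises(ConfigurationError, match="error_sd or icc"):
            ScoreModel("x", dist="normal", between_sd=1)
        with pytest.raises(ConfigurationError, match="n_subjects"):
            SimulationConfig(n_subjects=1)
        with pytest.raises(ConfigurationError, match="rho_construct"):
            SimulationConfig(rho_construct=1.5)


class TestDeterminism:
    def test_identical_config_gives_identical_cohort(self):
        c1 = simulate_cohort(small_config())
        c2 = simulate_cohort(small_config())
        assert c1.ground_truth.equals(c2.ground_truth)
        for s1, s2 in zip(c1.subjects, c2.subjects):
            assert np.array_equal(s1.epochs.counts, s2.epochs.counts)
            assert s1.aquaa_t0.to_dict() == s2.aquaa_t0.to_dict()
            assert s1.pase_t1.to_dict() == s2.pase_t1.to_dict()

    def test_different_seed_changes_cohort(self):
        c1 = simulate_cohort(small_config(seed=1))
        c2 = simulate_cohort(small_config(seed=2))
        assert not np.array_equal(c1.subjects[0].epochs.counts,
                                  c2.subjects[0].epochs.counts)

    def test_subject_streams_stable_under_cohort_growth(self):
        c1 = simulate_cohort(small_config(n_subjects=4))
        c2 = simulate_cohort(small_config(n_subjects=6))
        assert np.array_equal(
            c1.subjects[2].epochs.counts, c2.subjects[2].epochs.counts
        )


class TestEpochStream:
    def test_stream_geometry(self, rng):
        es = EpochSettings(days=7)
        series, cpm = simulate_epoch_stream(es, 0.0, rng)
        assert series.counts.size == 7 * 5760
        assert cpm > 0

    def test_full_week_nonwear_gives_all_zero_stream(self, rng):
        blocks = tuple(NonwearBlock(d, 0, 1440) for d in range(7))
        es = EpochSettings(days=7, nonwear_blocks=blocks)
        series, cpm = simulate_epoch_stream(es, 0.0, rng)
        assert (series.counts == 0).all()
        assert np.isnan(cpm)

    def test_planted_90_minute_block_detected_downstream(self, rng):
        es = EpochSettings(
            days=7, nonwear_blocks=(NonwearBlock(2, 600, 90),)
        )
        series, _ = simulate_epoch_stream(es, 0.0, rng)
        m = detect_nonwear(to_minutes(series))
        day2 = ~m.wear[2 * 1440 : 3 * 1440]
        assert day2[600:690].all()

    def test_planted_blocks_at_least_60_detected_shorter_not(self, rng):
        es = EpochSettings(
            days=7,
            nonwear_blocks=(NonwearBlock(1, 700, 60), NonwearBlock(3, 700, 45)),
        )
        series, _ = simulate_epoch_stream(es, 0.0, rng)
        m = detect_nonwear(to_minutes(series))
        assert (~m.wear[1 * 1440 + 700 : 1 * 1440 + 760]).all()
        # 45-min planted gap inside active wear stays wear
        assert m.wear[3 * 1440 + 700 : 3 * 1440 + 745].all()

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            EpochSettings(
                nonwear_blocks=(NonwearBlock(0, 600, 60), NonwearBlock(0, 630, 60))
            )

    def test_epochs_sum_back_to_minute_counts(self, rng):
        es = EpochSettings(days=1)
        series, _ = simulate_epoch_stream(es, 0.0, rng)
        m = to_minutes(series)
        assert m.counts_per_min.sum() == series.counts.sum()


class TestConstructCorrelation:
    def test_rank_correlation_near_target(self):
        # copula latents: questionnaire activity level vs accelerometer level
        from pametrics.synth import _draw_subject

        cfg = SimulationConfig(n_subjects=500, seed=7, rho_construct=0.15)
        draws = [_draw_subject(cfg, i) for i in range(cfg.n_subjects)]
        z_pa = [d[0] for d in draws]
        z_cpm = [d[1] for d in draws]
        rho = stats.spearmanr(z_pa, z_cpm).statistic
        assert 0.05 <= rho <= 0.25

    def test_cohort_level_correlation(self):
        # end-to-end: scored questionnaire totals vs realized counts/min
        cfg = SimulationConfig(n_subjects=150, seed=21, rho_construct=0.5)
        cohort = simulate_cohort(cfg)
        gt = cohort.ground_truth
        rho = stats.spearmanr(
            gt["pase_sum_t0"], gt["realized_counts_per_min"]
        ).statistic
        assert 0.3 <= rho <= 0.7


class TestInversion:
    def test_aquaa_round_trip_within_rounding(self, met_table):
        targets = {"sedentary": 3090.0, "light": 1063.0, "moderate": 196.0,
                   "vigorous": 34.0}
        resp = invert_aquaa(targets, "s1", "T0")
        s = score_aquaa(resp, met_table)
        assert s.sedentary_min == pytest.approx(targets["sedentary"], abs=3.5)
        assert s.light_min == pytest.approx(targets["light"], abs=3.5)
        assert s.moderate_min == pytest.approx(targets["moderate"], abs=3.5)
        assert s.vigorous_min == pytest.approx(targets["vigorous"], abs=3.5)

    def test_aquaa_markers_match_met_table(self, met_table):
        from pametrics.questionnaires import AquaaEntry, met_intensity_band

        for band, (category, activity, intensity, met) in AQUAA_MARKERS.items():
            e = AquaaEntry(category, activity, 1, 10, intensity)
            assert met_table.lookup(e) == met
            assert met_intensity_band(met) == band

    def test_pase_round_trip_within_grid_increment(self, pase_weights):
        # smallest non-zero weighted increment on the ordinal grid
        increment = min(
            w * pase_weights.frequency_days["seldom"] * pase_weights.duration_hours["lt1h"]
            for k, w in pase_weights.weights.items()
            if k != "work"
        )
        for target in (30.0, 86.0, 161.0, 400.0):
            resp = invert_pase(target, 1079.0, "s1", "T0", pase_weights)
            s = score_pase(resp, pase_weights)
            assert s.sum_score <= target + 1e-9
            assert target - s.sum_score < increment

    def test_pase_zero_target(self, pase_weights):
        resp = invert_pase(0.0, 0.0, "s1", "T0", pase_weights)
        s = score_pase(resp, pase_weights)
        assert s.sum_score == 0.0
        assert s.sedentary_min == 0.0


class TestParameterRecovery:
    def test_mean_icc_estimate_near_truth_n50(self):
        # 500 replicates at n=50: downstream estimator recovers the
        # configured population ICC to within 0.05
        rng = np.random.default_rng(404)
        m = ScoreModel("x", dist="normal", mean=100, between_sd=10, icc=0.6)
        estimates = []
        for _ in range(500):
            p = simulate_score_pairs(m, 50, rng)
            estimates.append(icc_oneway(variance_components(p))[0])
        assert np.mean(estimates) == pytest.approx(0.6, abs=0.05)


def test_simulate_paired_scores_covers_all_configured_scores():
    cfg = small_config()
    pairs = simulate_paired_scores(cfg)
    assert {p.name for p in pairs} == set(cfg.scores)
    for p in pairs:
        assert p.n == cfg.n_subjects
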