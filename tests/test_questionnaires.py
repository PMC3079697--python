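"""AQuAA and PASE scoring: band assignment, hand-computed scores, properties."""

import pytest
from hypothesis import given, settings, strategies as st

from pametrics.questionnaires import (
    AquaaEntry,
    AquaaResponse,
    PaseItem,
    PaseResponse,
    PaseWork,
    ScoringError,
    met_intensity_band,
    pase_hours_per_week,
    score_aquaa,
    score_pase,
)


def aquaa(entries, subject="s1", visit="T0"):
    return AquaaResponse(subject=subject, visit=visit, entries=entries)


class TestMetBands:
    @pytest.mark.parametrize(
        "met,band",
        [
            (1.5, "sedentary"),
            (1.999, "sedentary"),
            (2.0, "light"),
            (3.9, "light"),
            (4.0, "moderate"),
            (6.4, "moderate"),
            (6.5, "vigorous"),
            (12.0, "vigorous"),
        ],
    )
    def test_half_open_lower_inclusive_bands(self, met, band):
        assert met_intensity_band(met) == band

    def test_nonpositive_met_rejected(self):
        with pytest.raises(ValueError):
            met_intensity_band(0.0)


class TestAquaaScoring:
    def test_empty_response_scores_zero(self, met_table):
        s = score_aquaa(aquaa([]), met_table)
        assert s.total_score == 0 and s.total_pa_min == 0 and s.sedentary_min == 0

    def test_light_entry_hand_arithmetic(self, met_table):
        # 3 days x 60 min of walking at MET 3.0: 180 light min, 540 MET*min/wk
        e = AquaaEntry("leisure", "walking", 3, 60, "medium")
        assert met_table.lookup(e) == 3.0
        s = score_aquaa(aquaa([e]), met_table)
        assert s.light_min == 180
        assert s.total_score == 540

    def test_sedentary_entry_excluded_from_total_score(self, met_table):
        # MET < 2 accrues sedentary minutes but no MET*min
        e = AquaaEntry("leisure", "television", 7, 120, "high")  # MET 1.5
        s = score_aquaa(aquaa([e]), met_table)
        assert s.sedentary_min == 840
        assert s.total_score == 0

    def test_category_fallback_used_for_unknown_activity(self, met_table):
        e = AquaaEntry("sports", "curling", 1, 30, "medium")  # fallback MET 5.0
        s = score_aquaa(aquaa([e]), met_table)
        assert s.moderate_min == 30
        assert s.total_score == 150

    def test_unresolvable_activity_names_token(self, met_table):
        met_table_no_fallback = type(met_table)(
            activities={}, category_fallback={c: {} for c in
                ("commuting", "work_school", "household", "leisure", "sports")}
        )
        with pytest.raises(ScoringError, match="curling"):
            score_aquaa(
                aquaa([AquaaEntry("sports", "curling", 1, 30, "medium")]),
                met_table_no_fallback,
            )

    def test_additivity_of_concatenated_responses(self, met_table):
        e1 = AquaaEntry("leisure", "walking", 3, 60, "medium")
        e2 = AquaaEntry("sports", "jogging", 2, 30, "high")
        s1 = score_aquaa(aquaa([e1]), met_table)
        s2 = score_aquaa(aquaa([e2]), met_table)
        s12 = score_aquaa(aquaa([e1, e2]), met_table)
        assert s12.total_score == pytest.approx(s1.total_score + s2.total_score)
        assert s12.total_pa_min == pytest.approx(s1.total_pa_min + s2.total_pa_min)

    @settings(max_examples=50, derandomize=True)
    @given(
        days=st.integers(0, 7),
        minutes=st.floats(0, 600),
        category=st.sampled_from(("commuting", "household", "leisure", "sports")),
        intensity=st.sampled_from(("low", "medium", "high")),
    )
    def test_adding_entries_never_decreases_scores(
        self, met_table, days, minutes, category, intensity
    ):
        base = [AquaaEntry("leisure", "walking", 2, 30, "medium")]
        extra = AquaaEntry(category, "anything", days, minutes, intensity)
        s0 = score_aquaa(aquaa(base), met_table)
        s1 = score_aquaa(aquaa(base + [extra]), met_table)
        assert s1.total_score >= s0.total_score
        assert s1.total_pa_min + s1.sedentary_min >= s0.total_pa_min + s0.sedentary_min

    def test_hours_plus_minutes_normalised(self):
        resp = AquaaResponse.from_dict(
            {
                "subject": "s1",
                "visit": "T0",
                "entries": [
                    {
                        "category": "household",
                        "activity": "housework",
                        "days_per_week": 2,
                        "hours_per_day": 1,
                        "minutes_per_day": 30,
                        "intensity": "medium",
                    }
                ],
            }
        )
        assert resp.entries[0].minutes_per_day == 90


class TestPaseHours:
    def test_never_is_zero(self, pase_weights):
        assert pase_hours_per_week("never", None, pase_weights) == 0.0

    @pytest.mark.parametrize(
        "freq,dur,hours",
        [("sometimes", "h1to2", 3.5 * 1.5), ("often", "gt4h", 6 * 5.0),
         ("seldom", "h2to4", 1.5 * 3.0)],
    )
    def test_midpoint_products(self, pase_weights, freq, dur, hours):
        assert pase_hours_per_week(freq, dur, pase_weights) == pytest.approx(hours)

    def test_midpoints_monotone(self, pase_weights):
        freqs = ["never", "seldom", "sometimes", "often"]
        vals = [pase_weights.frequency_days[f] for f in freqs]
        assert vals == sorted(vals)


class TestPaseScoring:
    def test_all_never_scores_zero(self, pase_weights):
        items = [PaseItem(i, "never") for i in pase_weights.weights if i != "work"]
        resp = PaseResponse("s1", "T0", items=items)
        s = score_pase(resp, pase_weights)
        assert s.sum_score == 0 and s.total_pa_min == 0

    def test_single_item_hand_arithmetic(self, pase_weights):
        # walking weight 20, seldom (1.5 d/wk) x 2-4 h (3 h/d) = 4.5 h/wk -> 90
        resp = PaseResponse("s1", "T0", items=[PaseItem("walking", "seldom", "h2to4")])
        s = score_pase(resp, pase_weights)
        assert s.sum_score == pytest.approx(20 * 4.5)
        assert s.total_pa_min == pytest.approx(270)

    def test_sitting_only_work_counts_as_sedentary(self, pase_weights):
        resp = PaseResponse(
            "s1", "T0", work=PaseWork(worked=True, sitting_only=True, hours="h5to8")
        )
        s = score_pase(resp, pase_weights)
        assert s.sum_score == 0
        assert s.sedentary_min == pytest.approx(6.5 * 60)

    def test_active_work_enters_weighted_sum(self, pase_weights):
        resp = PaseResponse(
            "s1", "T0", work=PaseWork(worked=True, sitting_only=False, hours="gt8h")
        )
        s = score_pase(resp, pase_weights)
        assert s.sum_score == pytest.approx(pase_weights.weights["work"] * 10.0)

    def test_sitting_item_not_in_sum_score(self, pase_weights):
        resp = PaseResponse(
            "s1", "T0", items=[PaseItem("sitting", "often", "h2to4")]
        )
        s = score_pase(resp, pase_weights)
        assert s.sum_score == 0
        assert s.sedentary_min == pytest.approx(6 * 3 * 60)

    def test_unknown_item_raises(self, pase_weights):
        resp = PaseResponse("s1", "T0", items=[PaseItem("surfing", "often", "gt4h")])
        with pytest.raises(ScoringError, match="surfing"):
            score_pase(resp, pase_weights)

    def test_raising_category_never_decreases_sum(self, pase_weights):
        freqs = ["never", "seldom", "sometimes", "often"]
        durs = ["lt1h", "h1to2", "h2to4", "gt4h"]
        prev = -1.0
        for f in freqs[1:]:
            for d in durs:
                s = score_pase(
                    PaseResponse("s1", "T0", items=[PaseItem("walking", f, d)]),
                    pase_weights,
                )
                # within a frequency, longer duration never decreases the score
                assert s.sum_score >= 0
        for d in durs:
            scores = [
                score_pase(
                    PaseResponse("s", "T0", items=[PaseItem("walking", f, d)]),
                    pase_weights,
                ).sum_score
                for f in freqs[1:]
            ]
            assert scores == sorted(scores)

    def test_response_dict_round_trip(self, pase_weights):
        resp = PaseResponse(
            "s1",
            "T0",
            items=[PaseItem("walking", "often", "h1to2")],
            work=PaseWork(worked=True, sitting_only=False, hours="h1to4"),
        )
        back = PaseResponse.from_dict(resp.to_dict())
        assert score_pase(back, pase_weights) == score_pase(resp, pase_weights)
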