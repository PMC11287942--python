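"""Recall-day aggregation, energy shares, plausibility screening, participant means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietval import dietary
from dietval.config import KCAL_TO_KJ, EnergyFactors, PlausibilityConfig
from dietval.dietary import (DailyIntake, UnknownFoodCodeError, aggregate_day,
                             cohort_summary, energy_percent, participant_mean,
                             plausibility_flag)

from conftest import make_day
import _oracles


class TestAggregateDay:
    def test_energy_proportional_to_amount(self, simple_fct, simple_fgm):
        day = make_day([("A", 200.0)])
        out = aggregate_day(day, simple_fct, simple_fgm)
        assert out.values["energy_kj"] == pytest.approx(1000.0)
        assert out.values["fg_fruit_veg"] == pytest.approx(200.0)

    def test_empty_day_is_all_zero_and_flagged_low(self, simple_fct, simple_fgm):
        out = aggregate_day(make_day([]), simple_fct, simple_fgm)
        assert out.plausibility_flag == "low"
        grams = [out.values[c] for c in dietary.GRAM_FIELDS + dietary.GROUP_FIELDS]
        assert out.values["energy_kj"] == 0 and all(g == 0 for g in grams)
        assert np.isnan(out.values["protein_epct"])  # E% undefined at zero energy

    def test_three_item_day_matches_rowwise_sum_oracle(self, simple_fct, simple_fgm):
        items = [("A", 150.0), ("B", 80.0), ("C", 35.0)]
        out = aggregate_day(make_day(items), simple_fct, simple_fgm)
        comp_rows = {c: simple_fct.loc[c].to_dict() for c in simple_fct.index}
        expected = _oracles.rowwise_day_totals(items, comp_rows)
        for col in ("energy_kj",) + dietary.GRAM_FIELDS:
            assert out.values[col] == pytest.approx(expected[col], rel=1e-12)
        # C belongs to two groups: both receive the full amount
        assert out.values["fg_red_meat"] == out.values["fg_sweet_savoury_treats"] == 35.0

    def test_unknown_code_is_hard_error_naming_the_code(self, simple_fct, simple_fgm):
        with pytest.raises(UnknownFoodCodeError, match="ZZZ"):
            aggregate_day(make_day([("ZZZ", 10.0)]), simple_fct, simple_fgm)

    def test_density_fields(self, simple_fct, simple_fgm):
        out = aggregate_day(make_day([("B", 300.0)]), simple_fct, simple_fgm)
        energy = out.values["energy_kj"]
        assert out.values["fibre_g_per_mj"] == pytest.approx(
            out.values["fibre_g"] / (energy / 1000.0))
        assert out.values["wholegrain_g_per_10mj"] == pytest.approx(
            out.values["wholegrain_g"] / (energy / 10000.0))


class TestEnergyPercent:
    @pytest.mark.parametrize("grams, factor, energy, expected", [
        (50.0, 17.0, 8500.0, 10.0),
        (0.0, 37.0, 8000.0, 0.0),
    ])
    def test_round_numbers(self, grams, factor, energy, expected):
        assert energy_percent(grams, factor, energy) == pytest.approx(expected)

    def test_zero_energy_returns_missing(self):
        assert np.isnan(energy_percent(10.0, 17.0, 0.0))

    def test_fixture_day_matches_hand_calculation(self, simple_fct, simple_fgm):
        out = aggregate_day(make_day([("A", 100.0), ("C", 50.0)]), simple_fct, simple_fgm)
        protein = 2.0 + 2.5
        energy = 500.0 + 1000.0
        assert out.values["protein_epct"] == pytest.approx(100 * protein * 17 / energy)


class TestPlausibility:
    @pytest.mark.parametrize("kcal, expected", [
        (3600.0, "high"),
        (2000.0, "ok"),
        (3500.0, "ok"),   # strict inequality: 'exceeded'
        (800.0, "ok"),    # strict inequality: 'less than'
        (500.0, "low"),
    ])
    def test_thresholds(self, kcal, expected):
        assert plausibility_flag(kcal * KCAL_TO_KJ) == expected

    def test_thresholds_are_config(self):
        cfg = PlausibilityConfig(low_kcal=1000.0, high_kcal=2000.0)
        assert plausibility_flag(900.0 * KCAL_TO_KJ, cfg) == "low"

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            plausibility_flag(-1.0)


def _daily(energy, red=0.0, processed=0.0, pid="p1", method="web_recall", day=1):
    values = pd.Series(0.0, index=list(dietary.DAILY_FIELDS))
    values["energy_kj"] = energy
    values["fg_red_meat"] = red
    values["fg_processed_meat"] = processed
    return DailyIntake(pid, method, day, values, plausibility_flag(energy))


class TestParticipantMean:
    def test_identical_days_idempotent(self):
        days = [_daily(9000.0, red=40.0, day=i) for i in (1, 2, 3)]
        pm = participant_mean(days)
        assert pm.n_days == 3
        assert pm.values["energy_kj"] == pytest.approx(9000.0)

    def test_midpoint(self):
        pm = participant_mean([_daily(8000.0, day=1), _daily(10000.0, day=2)])
        assert pm.values["energy_kj"] == pytest.approx(9000.0)
        assert pm.n_days == 2  # two-day participants are study-conformant

    def test_weekly_meat_is_seven_times_daily_mean(self):
        pm = participant_mean([_daily(9000.0, red=30.0, processed=20.0, day=1),
                               _daily(9000.0, red=50.0, processed=0.0, day=2)])
        assert pm.values["red_processed_meat_weekly_g"] == pytest.approx(7 * (40.0 + 10.0))

    def test_flagged_days_retained_by_default_excluded_on_request(self):
        days = [_daily(2000.0, day=1), _daily(9000.0, day=2)]  # first is 'low'
        assert participant_mean(days).values["energy_kj"] == pytest.approx(5500.0)
        kept = participant_mean(days, exclude_flagged=True)
        assert kept.values["energy_kj"] == pytest.approx(9000.0)
        assert kept.n_days == 1

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            participant_mean([])


class TestCohortSummary:
    def test_two_point_sd(self):
        df = pd.DataFrame({
            "participant_id": ["p1", "p2"], "method": ["web_recall"] * 2,
            "energy_kj": [9000.0, 11000.0],
        })
        out = cohort_summary(df)
        assert out.loc["energy_kj", "web_recall_mean"] == pytest.approx(10000.0)
        assert out.loc["energy_kj", "web_recall_sd"] == pytest.approx(1414.2, abs=0.1)

    def test_matches_independent_mean_sd_oracle(self, rng):
        vals = rng.normal(50, 10, 30)
        df = pd.DataFrame({"participant_id": [f"p{i}" for i in range(30)],
                           "method": ["web_recall"] * 30, "x": vals})
        out = cohort_summary(df)
        m, s = _oracles.mean_sd(vals)
        assert out.loc["x", "web_recall_mean"] == pytest.approx(m, rel=1e-12)
        assert out.loc["x", "web_recall_sd"] == pytest.approx(s, rel=1e-12)

    def test_single_participant_rejected(self):
        df = pd.DataFrame({"participant_id": ["p1"], "method": ["web_recall"],
                           "energy_kj": [9000.0]})
        with pytest.raises(ValueError):
            cohort_summary(df)


items_strategy = st.lists(
    st.tuples(st.sampled_from(["A", "B", "C"]),
              st.floats(0.0, 500.0, allow_nan=False)),
    min_size=0, max_size=8,
)


class TestAggregationProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(items_a=items_strategy, items_b=items_strategy)
    def test_linearity_over_item_concatenation(self, simple_fct, simple_fgm,
                                               items_a, items_b):
        both = aggregate_day(make_day(items_a + items_b), simple_fct, simple_fgm)
        a = aggregate_day(make_day(items_a), simple_fct, simple_fgm)
        b = aggregate_day(make_day(items_b), simple_fct, simple_fgm)
        for col in ("energy_kj",) + dietary.GRAM_FIELDS + dietary.GROUP_FIELDS:
            assert both.values[col] == pytest.approx(a.values[col] + b.values[col],
                                                     rel=1e-9, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(items=items_strategy, c=st.floats(0.1, 5.0, allow_nan=False))
    def test_scaling_amounts_scales_grams_not_epct(self, simple_fct, simple_fgm,
                                                   items, c):
        base = aggregate_day(make_day(items), simple_fct, simple_fgm)
        scaled = aggregate_day(make_day([(k, a * c) for k, a in items]),
                               simple_fct, simple_fgm)
        for col in ("energy_kj",) + dietary.GRAM_FIELDS + dietary.GROUP_FIELDS:
            assert scaled.values[col] == pytest.approx(c * base.values[col],
                                                       rel=1e-9, abs=1e-9)
        for col in dietary.EPCT_FIELDS:
            if not np.isnan(base.values[col]):
                assert scaled.values[col] == pytest.approx(base.values[col], rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(items=items_strategy)
    def test_item_order_irrelevant(self, simple_fct, simple_fgm, items):
        fwd = aggregate_day(make_day(items), simple_fct, simple_fgm)
        rev = aggregate_day(make_day(items[::-1]), simple_fct, simple_fgm)
        pd.testing.assert_series_equal(fwd.values, rev.values, rtol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(energies=st.lists(st.floats(1000.0, 15000.0), min_size=1, max_size=3))
    def test_mean_commutes_with_field_selection(self, energies):
        days = [_daily(e, day=i % 3 + 1) for i, e in enumerate(energies)]
        pm = participant_mean(days)
        assert pm.values["energy_kj"] == pytest.approx(np.mean(energies), rel=1e-12)
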