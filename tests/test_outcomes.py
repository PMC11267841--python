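"""Reach, weighing metrics, mechanisms of change, and Cohen's kappa."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poincare_fidelity.data_model import IntegrityError, Period, ScoringRules
from poincare_fidelity.outcomes import (
    cohens_kappa,
    hypotension_proportion,
    reach,
    summarize,
    weekly_weighins,
    weighing_achieved_expected,
    weight_change,
)
from poincare_fidelity.scoring import score_cohort

from conftest import make_day, make_stay


def stay_with_weighins(n_days, weighed_days, period=Period.CONTROL, **kw):
    days = [
        make_day(
            day_index=d,
            period=period,
            weight_kg=70.0 if d in weighed_days else None,
        )
        for d in range(1, n_days + 1)
    ]
    return make_stay(days, admission_weight_kg=70.0, **kw)


@pytest.mark.parametrize(
    "included,expected,pct", [(43, 30, pytest.approx(143.33, abs=0.01)), (30, 30, 100.0), (0, 30, 0.0)]
)
def test_reach_percentage(included, expected, pct):
    assert reach(included, expected) == pct


def test_reach_rejects_zero_expected():
    with pytest.raises(ValueError):
        reach(10, 0)


@pytest.mark.parametrize(
    "n_days,weighed,expected",
    [
        (14, range(1, 15), 7.0),  # daily weighing ceiling
        (14, {1, 5, 9, 13}, 2.0),
        (7, {1}, 1.0),  # weekly standard of care
    ],
)
def test_weekly_weighins(n_days, weighed, expected):
    assert weekly_weighins(stay_with_weighins(n_days, set(weighed))) == expected


def test_achieved_over_expected_is_period_dependent():
    """Control is held to weekly weighing, intervention to the daily window."""
    rules = ScoringRules()
    # intervention, 10-day stay fully weighed on days 2..10 -> 9/9 window days
    intv = stay_with_weighins(
        10, set(range(2, 11)), period=Period.INTERVENTION
    )
    assert weighing_achieved_expected(intv, rules) == 100.0
    # control, 14-day stay, 8 weigh-ins against 2 expected weekly blocks
    ctrl = stay_with_weighins(14, set(range(1, 9)), period=Period.CONTROL)
    assert weighing_achieved_expected(ctrl, rules) == 400.0
    none = stay_with_weighins(14, set(), period=Period.CONTROL)
    assert weighing_achieved_expected(none, rules) == 0.0


def test_hypotension_counts_patients_not_days():
    def stay(pid, hypo_days):
        days = [
            make_day(patient_id=pid, day_index=d, weight_kg=70.0, hypotension=d in hypo_days)
            for d in range(1, 6)
        ]
        return make_stay(days)

    group = [stay("a", {2, 3, 4, 5}), stay("b", {1}), stay("c", set()), stay("d", set())]
    assert hypotension_proportion(group) == (50.0, 2)
    assert hypotension_proportion([stay("c", set())]) == (0.0, 0)


def test_weight_change_and_missing_discharge():
    s = stay_with_weighins(5, {1}, discharge_weight_kg=68.0)
    assert weight_change(s) == -2.0
    s2 = stay_with_weighins(5, {1})
    assert weight_change(s2) is None


class TestCohensKappa:
    def test_perfect_agreement_is_one_even_for_single_category(self):
        assert cohens_kappa(["x"] * 5, ["x"] * 5) == 1.0
        assert cohens_kappa([1, 2, 3], [1, 2, 3]) == 1.0

    def test_two_by_two_closed_form(self):
        """Agreement table (45, 5; 15, 35): p_o = 0.8, p_e = 0.5, kappa = 0.6."""
        a = ["A"] * 50 + ["B"] * 50
        b = ["A"] * 45 + ["B"] * 5 + ["A"] * 15 + ["B"] * 35
        assert cohens_kappa(a, b) == pytest.approx(0.6, abs=1e-12)

    def test_chance_level_agreement_is_near_zero(self):
        rng = np.random.default_rng(0)
        a = ["A"] * 2000
        b = list(rng.choice(["A", "B"], size=2000))
        assert abs(cohens_kappa(a, b)) < 1e-9  # constant coder: p_o == p_e exactly

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 2], [1])

    @given(st.lists(st.tuples(st.sampled_from("abc"), st.sampled_from("abc")), min_size=2, max_size=40))
    def test_symmetry_and_permutation_invariance(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        k_ab = cohens_kappa(a, b)
        assert k_ab == pytest.approx(cohens_kappa(b, a), abs=1e-12)
        order = np.random.default_rng(1).permutation(len(a))
        assert cohens_kappa([a[i] for i in order], [b[i] for i in order]) == pytest.approx(
            k_ab, abs=1e-12
        )

    def test_matches_statsmodels_on_random_codes(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa
        import pandas as pd

        rng = np.random.default_rng(7)
        a = rng.choice(["u", "v", "w"], size=300)
        b = np.where(rng.random(300) < 0.6, a, rng.choice(["u", "v", "w"], size=300))
        table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
        assert cohens_kappa(a, b) == pytest.approx(
            float(sm_kappa(table, return_results=False)), abs=1e-9
        )


def two_patient_group():
    """Hand-computable group: spreadsheet-style oracle in the assertions."""
    s1 = make_stay(
        [
            make_day(patient_id="p1", day_index=1, weight_kg=70.0, intake_ml=2000.0),
            make_day(patient_id="p1", day_index=2, weight_kg=73.0, intake_ml=2000.0),
            make_day(patient_id="p1", day_index=3, weight_kg=None, intake_ml=2000.0),
            make_day(patient_id="p1", day_index=4, weight_kg=69.0, intake_ml=2000.0, hypotension=True),
        ],
        admission_weight_kg=70.0,
        discharge_weight_kg=69.0,
    )
    s2 = make_stay(
        [
            make_day(patient_id="p2", day_index=1, weight_kg=80.0, intake_ml=1000.0),
            make_day(patient_id="p2", day_index=2, weight_kg=81.0, intake_ml=700.0),
            make_day(patient_id="p2", day_index=3, weight_kg=79.0, intake_ml=1000.0),
        ],
        admission_weight_kg=80.0,
        discharge_weight_kg=79.0,
    )
    return [s1, s2]


def test_summarize_two_patient_group_against_hand_computation():
    stays = two_patient_group()
    results = score_cohort(stays)
    (row,) = summarize(stays, results, {("A", Period.CONTROL): 4})
    assert row.n_patients == 2
    assert row.reach_pct == 50.0
    # weigh-ins: p1 3/4 days, p2 3/3 days -> weekly 5.25 and 7.0
    assert row.weekly_weighins_mean == pytest.approx((5.25 + 7.0) / 2)
    # control expectation: one weigh-in per started week -> 300 % and 300 %
    assert row.weighing_achieved_expected_pct == pytest.approx(300.0)
    # p1: day2 deviation (73 > 72, 2000 intake, no drug), day4 not overloaded
    #     -> raw 100*(1-1/3), weighed 2/3
    # p2: never above threshold (81 <= 82, 79 <= 80) -> raw 100, weighed 2/2
    p1 = 100.0 * (1 - 1 / 3) * (2 / 3)
    assert row.score_mean == pytest.approx((p1 + 100.0) / 2)
    assert row.hypotension_pct == 50.0 and row.hypotension_n == 1
    assert row.weight_change_mean_kg == pytest.approx(-1.0)


def test_summarize_single_patient_group_has_absent_sds():
    stays = two_patient_group()[:1]
    results = score_cohort(stays)
    (row,) = summarize(stays, results)
    assert row.n_patients == 1
    assert row.weekly_weighins_sd is None
    assert row.score_sd is None
    assert row.weight_change_sd_kg is None
    assert row.reach_pct is None  # no enrolment counts supplied


def test_summarize_rejects_unknown_groups():
    stays = two_patient_group()
    results = score_cohort(stays)
    with pytest.raises(IntegrityError, match="B"):
        summarize(stays, results, {("B", Period.CONTROL): 4})
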