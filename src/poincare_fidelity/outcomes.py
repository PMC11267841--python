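"""Descriptive process-evaluation outcomes per ICU and trial period.

Covers reach (included over expected enrolment), dose and fidelity
(weekly weigh-ins per patient, achieved-over-expected weighing, and the
per-ICU mean exposure score), and mechanisms of change (weight change
between admission and discharge, and the proportion of patients with at
least one hypotension episode), plus an unweighted Cohen's kappa for
inter-coder agreement on nominal codes.

The expected number of weigh-ins is period-dependent: the control
period is held to the weekly standard of care (one weigh-in per started
7-day block of the stay), the intervention period to the daily protocol
(one per day of the stay inside the Day 2-14 window).  Achieved counts
every weigh-in of the stay, so the control-period ratio routinely
exceeds 100 %.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .data_model import (
    ExposureResult,
    IcuPeriodSummary,
    IntegrityError,
    PatientStay,
    Period,
    ScoringRules,
)

__all__ = [
    "reach",
    "weekly_weighins",
    "weighing_achieved_expected",
    "hypotension_proportion",
    "weight_change",
    "cohens_kappa",
    "summarize",
]

logger = logging.getLogger(__name__)


def reach(n_included: int, n_expected: int) -> float:
    """Included patients as a percentage of planned enrolment."""
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    return 100.0 * n_included / n_expected


def _n_weighins(stay: PatientStay) -> int:
    return sum(1 for rec in stay.days if rec.weight_kg is not None)


def weekly_weighins(stay: PatientStay) -> float:
    """Weigh-ins per 7 days of stay (7 = weighed daily)."""
    if stay.los_days < 1:
        raise ValueError("los_days must be >= 1")
    return 7.0 * _n_weighins(stay) / stay.los_days


def expected_weighins(stay: PatientStay, rules: ScoringRules | None = None) -> int:
    """Period-dependent expected number of weigh-ins for one stay."""
    rules = rules or ScoringRules()
    if stay.period is Period.CONTROL:
        return math.ceil(stay.los_days / rules.control_expected_block_days)
    return max(0, min(stay.los_days, rules.window_end_day) - rules.window_start_day + 1)


def weighing_achieved_expected(
    stay: PatientStay, rules: ScoringRules | None = None
) -> float | None:
    """Achieved weigh-ins over the period's expectation, as a percentage.

    Returns ``None`` (with a warning) when the expectation is zero,
    e.g. an intervention stay ending before the scoring window.
    """
    expected = expected_weighins(stay, rules)
    if expected == 0:
        logger.warning(
            "patient %s: zero expected weigh-ins; excluded from weighing ratio",
            stay.patient_id,
        )
        return None
    return 100.0 * _n_weighins(stay) / expected


def hypotension_proportion(
    stays: Iterable[PatientStay],
) -> tuple[float, int]:
    """(% of patients with >= 1 hypotensive day, count) for one group."""
    stays = list(stays)
    if not stays:
        raise ValueError("group must be non-empty")
    n_flagged = sum(1 for s in stays if any(rec.hypotension for rec in s.days))
    return 100.0 * n_flagged / len(stays), n_flagged


def weight_change(stay: PatientStay) -> float | None:
    """Discharge minus admission weight (kg); absent without a discharge weight."""
    if stay.discharge_weight_kg is None:
        return None
    return stay.discharge_weight_kg - stay.admission_weight_kg


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Unweighted Cohen's kappa between two coders' nominal labels.

    kappa = (p_o - p_e) / (1 - p_e); returns 1.0 for perfect agreement
    even when a single category leaves no room for chance correction.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label sequences differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if len(labels_a) == 0:
        raise ValueError("label sequences must be non-empty")
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if (a == b).all():
        return 1.0
    return float(cohen_kappa_score(a, b))


def _mean_sd(values: Sequence[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return mean, sd


def summarize(
    stays: Iterable[PatientStay],
    exposure_results: Iterable[ExposureResult],
    enrolment_counts: Mapping[tuple[str, Period], int] | None = None,
    rules: ScoringRules | None = None,
) -> list[IcuPeriodSummary]:
    """Assemble one summary row per (ICU, period).

    ``enrolment_counts`` maps ``(icu_id, period)`` to planned enrolment;
    when omitted, reach is reported as absent.  A group present in the
    exposure results but missing from the stays (or vice versa with a
    defined score) raises :class:`IntegrityError` naming the group.
    """
    rules = rules or ScoringRules()
    by_group: dict[tuple[str, Period], list[PatientStay]] = defaultdict(list)
    for stay in stays:
        by_group[(stay.icu_id, stay.period)].append(stay)
    scores: dict[tuple[str, Period], list[float]] = defaultdict(list)
    for res in exposure_results:
        key = (res.icu_id, res.period)
        if key not in by_group:
            raise IntegrityError(f"exposure results reference unknown group {key}")
        scores[key].append(res.final_score)

    if enrolment_counts is not None:
        unknown = set(enrolment_counts) - set(by_group)
        if unknown:
            raise IntegrityError(
                f"enrolment counts reference unknown group(s) {sorted(unknown)}"
            )

    rows: list[IcuPeriodSummary] = []
    for key in sorted(by_group, key=lambda k: (k[0], k[1].value)):
        icu_id, period = key
        group = by_group[key]
        if not scores[key]:
            logger.warning("group %s has no defined exposure score", key)
        wk = [weekly_weighins(s) for s in group]
        wk_mean, wk_sd = _mean_sd(wk)
        ratios = [
            r for r in (weighing_achieved_expected(s, rules) for s in group) if r is not None
        ]
        ratio_mean, _ = _mean_sd(ratios)
        score_mean, score_sd = _mean_sd(scores[key])
        hypo_pct, hypo_n = hypotension_proportion(group)
        deltas = [d for d in (weight_change(s) for s in group) if d is not None]
        delta_mean, delta_sd = _mean_sd(deltas)
        reach_pct = None
        if enrolment_counts is not None and key in enrolment_counts:
            reach_pct = reach(len(group), enrolment_counts[key])
        rows.append(
            IcuPeriodSummary(
                icu_id=icu_id,
                period=period,
                n_patients=len(group),
                reach_pct=reach_pct,
                weekly_weighins_mean=wk_mean,
                weekly_weighins_sd=wk_sd,
                weighing_achieved_expected_pct=ratio_mean,
                score_mean=score_mean if score_mean is not None else float("nan"),
                score_sd=score_sd,
                hypotension_pct=hypo_pct,
                hypotension_n=hypo_n,
                weight_change_mean_kg=delta_mean,
                weight_change_sd_kg=delta_sd,
            )
        )
    return rows
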