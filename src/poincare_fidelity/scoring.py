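"""Per-patient score of actual exposure to the fluid-balance strategy.

The strategy under evaluation: weigh the patient daily between Day 2
and Day 14 after ICU admission; whenever the daily weight exceeds a
day-indexed overload threshold (admission weight + 2 kg on Day 2,
admission weight on Days 3-7, admission weight − 2 kg on Days 8-14),
respond with a >= 30 % restriction of water and salt intake versus the
previous day, diuretics, or ultrafiltration — unless restriction is
contraindicated (hypotension, Na > 155 mmol/L, K < 2.8 mmol/L, or
RIFLE >= risk).

A *deviation* is an overloaded, non-contraindicated day with none of the
compliant responses.  The raw score is 100 x (1 − deviation rate); the
final score weights it by the proportion of in-window days actually
weighed, giving a 0-100 index where 0 is minimal and 100 maximal
delivered dose.  Computed per patient and averaged per ICU x period, the
score quantifies fidelity/dose during the intervention period and
contamination during the control period.
"""

from __future__ import annotations

import enum
import logging
from typing import Iterable, NamedTuple

import pandas as pd

from .data_model import (
    ExposureResult,
    PatientDayRecord,
    PatientStay,
    Period,
    ScoringRules,
)

__all__ = [
    "Overload",
    "day_threshold",
    "is_overloaded",
    "is_contraindicated",
    "is_compliant_response",
    "count_deviations",
    "patient_score",
    "score_cohort",
    "icu_period_score",
    "DeviationCounts",
]

logger = logging.getLogger(__name__)


class Overload(enum.Enum):
    """Tri-state overload status of a day: unknown when the weight is absent."""

    OVERLOADED = "overloaded"
    NOT_OVERLOADED = "not_overloaded"
    UNKNOWN = "unknown"


def day_threshold(
    day_index: int, admission_weight_kg: float, rules: ScoringRules | None = None
) -> float:
    """Overload threshold (kg) for a given in-window day.

    Raises ``ValueError`` outside the scoring window.
    """
    rules = rules or ScoringRules()
    if not rules.window_start_day <= day_index <= rules.window_end_day:
        raise ValueError(
            f"day {day_index} outside scoring window "
            f"[{rules.window_start_day}, {rules.window_end_day}]"
        )
    if day_index < rules.mid_band[0]:
        return admission_weight_kg + rules.early_offset_kg
    if day_index <= rules.mid_band[1]:
        return admission_weight_kg + rules.mid_offset_kg
    return admission_weight_kg + rules.late_offset_kg


def is_overloaded(
    record: PatientDayRecord,
    admission_weight_kg: float,
    rules: ScoringRules | None = None,
) -> Overload:
    """Overload status of a day record; strict inequality, unknown if unweighed."""
    rules = rules or ScoringRules()
    if record.weight_kg is None:
        return Overload.UNKNOWN
    threshold = day_threshold(record.day_index, admission_weight_kg, rules)
    return Overload.OVERLOADED if record.weight_kg > threshold else Overload.NOT_OVERLOADED


def is_contraindicated(
    record: PatientDayRecord, rules: ScoringRules | None = None
) -> bool:
    """True iff water/salt restriction is contraindicated that day.

    Hypotension, Na > 155 mmol/L, K < 2.8 mmol/L or RIFLE >= risk;
    absent labs contribute False.  Strict inequalities.
    """
    rules = rules or ScoringRules()
    if record.hypotension:
        return True
    if record.serum_na_mmol_l is not None and record.serum_na_mmol_l > rules.na_max_mmol_l:
        return True
    if record.serum_k_mmol_l is not None and record.serum_k_mmol_l < rules.k_min_mmol_l:
        return True
    return record.rifle_level >= rules.rifle_contraindication_min


def is_compliant_response(
    record: PatientDayRecord,
    previous_intake_ml: float | None,
    rules: ScoringRules | None = None,
) -> bool:
    """True iff the day shows any protocol response to fluid overload.

    Diuretics, ultrafiltration, or intake cut by at least the
    restriction fraction versus the previous day's intake.  Exactly 30 %
    restriction counts as compliant.  With no previous-day intake (or a
    previous intake of zero) the restriction branch is unevaluable and
    contributes False; the treatment branches still apply.
    """
    rules = rules or ScoringRules()
    if record.diuretics_given or record.ultrafiltration_ml > 0:
        return True
    if previous_intake_ml is None or previous_intake_ml <= 0:
        return False
    return record.intake_ml <= (1.0 - rules.restriction_fraction) * previous_intake_ml


class DeviationCounts(NamedTuple):
    n_deviations: int
    n_overload_days: int
    n_window_days: int
    n_weighed_window: int


def count_deviations(
    stay: PatientStay, rules: ScoringRules | None = None
) -> DeviationCounts:
    """Count strategy deviations over the stay's scoring window.

    A deviation is a weighed, overloaded, non-contraindicated day with
    no compliant response.  Unweighed days are unobservable and
    contribute nothing; contraindicated overload days are never
    deviations, whatever was given.  ``n_window_days`` is the number of
    stay days falling inside the window (zero when the stay ends before
    the window opens).
    """
    rules = rules or ScoringRules()
    window_lo = rules.window_start_day
    window_hi = min(stay.los_days, rules.window_end_day)
    if window_hi < window_lo:
        return DeviationCounts(0, 0, 0, 0)
    n_window_days = window_hi - window_lo + 1

    by_day = {rec.day_index: rec for rec in stay.days}
    n_weighed = 0
    n_overload = 0
    n_dev = 0
    for d in range(window_lo, window_hi + 1):
        rec = by_day.get(d)
        if rec is None or rec.weight_kg is None:
            continue
        n_weighed += 1
        if is_overloaded(rec, stay.admission_weight_kg, rules) is not Overload.OVERLOADED:
            continue
        n_overload += 1
        if is_contraindicated(rec, rules):
            continue
        prev = by_day.get(d - 1)
        prev_intake = prev.intake_ml if prev is not None else None
        if not is_compliant_response(rec, prev_intake, rules):
            n_dev += 1
    return DeviationCounts(n_dev, n_overload, n_window_days, n_weighed)


def patient_score(
    stay: PatientStay, rules: ScoringRules | None = None
) -> ExposureResult | None:
    """Compute the 0-100 exposure score for one stay.

    Returns ``None`` (with a warning) when the stay has no day inside
    the scoring window, in which case the score is undefined and the
    patient is excluded from aggregation.
    """
    rules = rules or ScoringRules()
    counts = count_deviations(stay, rules)
    if counts.n_window_days == 0:
        logger.warning(
            "patient %s: stay ends before the scoring window; score undefined",
            stay.patient_id,
        )
        return None
    denom = stay.los_days if rules.denominator == "full_los" else counts.n_window_days
    raw = 100.0 * (1.0 - counts.n_deviations / denom)
    weigh_proportion = counts.n_weighed_window / counts.n_window_days
    result = ExposureResult(
        patient_id=stay.patient_id,
        icu_id=stay.icu_id,
        period=stay.period,
        n_window_days=counts.n_window_days,
        n_weighed_window=counts.n_weighed_window,
        weigh_proportion=weigh_proportion,
        n_overload_days=counts.n_overload_days,
        n_deviations=counts.n_deviations,
        raw_score=raw,
        final_score=raw * weigh_proportion,
    )
    result.validate()
    return result


def score_cohort(
    stays: Iterable[PatientStay], rules: ScoringRules | None = None
) -> list[ExposureResult]:
    """Score every stay; stays with an undefined score are dropped with a warning."""
    rules = rules or ScoringRules()
    results = []
    for stay in stays:
        res = patient_score(stay, rules)
        if res is not None:
            results.append(res)
    return results


def icu_period_score(results: Iterable[ExposureResult]) -> pd.DataFrame:
    """Mean and sample standard deviation (n−1) of final scores per ICU x period.

    Single-patient groups report an absent (NaN) standard deviation.
    """
    rows = [
        {
            "icu_id": r.icu_id,
            "period": r.period.value,
            "final_score": r.final_score,
        }
        for r in results
    ]
    if not rows:
        logger.warning("no defined exposure results to aggregate")
        return pd.DataFrame(columns=["icu_id", "period", "n", "score_mean", "score_sd"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["icu_id", "period"], sort=True)["final_score"]
        .agg(n="count", score_mean="mean", score_sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return out
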