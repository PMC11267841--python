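"""Shared fixtures: hand-built stays, random-stay factories, naive oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from poincare_fidelity.data_model import (
    PatientDayRecord,
    PatientStay,
    Period,
    RifleLevel,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_day(
    patient_id="p1",
    icu_id="A",
    period=Period.CONTROL,
    day_index=1,
    weight_kg=None,
    intake_ml=2000.0,
    diuretics_given=False,
    ultrafiltration_ml=0.0,
    serum_na_mmol_l=140.0,
    serum_k_mmol_l=4.0,
    rifle_level=RifleLevel.NONE,
    hypotension=False,
) -> PatientDayRecord:
    return PatientDayRecord(
        patient_id=patient_id,
        icu_id=icu_id,
        period=period,
        day_index=day_index,
        weight_kg=weight_kg,
        intake_ml=intake_ml,
        diuretics_given=diuretics_given,
        ultrafiltration_ml=ultrafiltration_ml,
        serum_na_mmol_l=serum_na_mmol_l,
        serum_k_mmol_l=serum_k_mmol_l,
        rifle_level=rifle_level,
        hypotension=hypotension,
    )


def make_stay(days, admission_weight_kg=70.0, discharge_weight_kg=None, los_days=None, **kw):
    first = days[0]
    stay = PatientStay(
        patient_id=first.patient_id,
        icu_id=first.icu_id,
        period=first.period,
        admission_weight_kg=admission_weight_kg,
        discharge_weight_kg=discharge_weight_kg,
        los_days=los_days or max(d.day_index for d in days),
        days=sorted(days, key=lambda d: d.day_index),
        **kw,
    )
    stay.validate()
    return stay


@pytest.fixture
def worked_patient() -> PatientStay:
    """The 4-scored-day reference stay (admission 70 kg, LOS 5).

    Day 2: weight 73 > 72 threshold, intake cut only 25 % from Day 1's
    2000 mL, no treatment -> the single deviation.  Day 3: overloaded
    but diuretics given.  Day 4: 69.5 below threshold.  Day 5:
    overloaded but hypotensive, hence contraindicated.
    """
    days = [
        make_day(day_index=1, weight_kg=70.0, intake_ml=2000.0),
        make_day(day_index=2, weight_kg=73.0, intake_ml=1500.0),
        make_day(day_index=3, weight_kg=71.0, intake_ml=2000.0, diuretics_given=True),
        make_day(day_index=4, weight_kg=69.5, intake_ml=2000.0),
        make_day(day_index=5, weight_kg=71.0, intake_ml=2000.0, hypotension=True),
    ]
    return make_stay(days, admission_weight_kg=70.0, discharge_weight_kg=71.0)


def random_stay(seed: int, max_los: int = 16) -> PatientStay:
    """A random small stay with mixed missingness and contraindications."""
    rng = np.random.default_rng(seed)
    los = int(rng.integers(1, max_los + 1))
    admission = float(rng.uniform(50, 100))
    days = []
    for d in range(1, los + 1):
        weighed = rng.random() < 0.7
        days.append(
            make_day(
                patient_id=f"r{seed}",
                day_index=d,
                weight_kg=round(admission + float(rng.uniform(-4, 5)), 2)
                if weighed
                else None,
                intake_ml=round(float(rng.uniform(500, 3000)), 1),
                diuretics_given=bool(rng.random() < 0.15),
                ultrafiltration_ml=1000.0 if rng.random() < 0.08 else 0.0,
                serum_na_mmol_l=None
                if rng.random() < 0.1
                else round(float(rng.uniform(130, 160)), 1),
                serum_k_mmol_l=None
                if rng.random() < 0.1
                else round(float(rng.uniform(2.4, 5.2)), 2),
                rifle_level=RifleLevel(int(rng.integers(0, 6)))
                if rng.random() < 0.2
                else RifleLevel.NONE,
                hypotension=bool(rng.random() < 0.15),
            )
        )
    return make_stay(
        days,
        admission_weight_kg=round(admission, 2),
        discharge_weight_kg=round(admission + float(rng.uniform(-5, 5)), 2),
    )


def oracle_patient_score(stay: PatientStay):
    """Naive day-loop re-implementation of the exposure score.

    Deliberately written from the protocol wording, independent of the
    package internals: returns (n_dev, n_overload, n_window, n_weighed,
    raw, weigh_prop, final) or None when the stay never enters the
    Day 2-14 window.
    """
    records = {d.day_index: d for d in stay.days}
    window = [d for d in range(2, 15) if d <= stay.los_days]
    if not window:
        return None
    n_dev = n_over = n_weighed = 0
    for d in window:
        rec = records.get(d)
        if rec is None or rec.weight_kg is None:
            continue
        n_weighed += 1
        if d == 2:
            threshold = stay.admission_weight_kg + 2.0
        elif d <= 7:
            threshold = stay.admission_weight_kg
        else:
            threshold = stay.admission_weight_kg - 2.0
        if not rec.weight_kg > threshold:
            continue
        n_over += 1
        contra = (
            rec.hypotension
            or (rec.serum_na_mmol_l is not None and rec.serum_na_mmol_l > 155.0)
            or (rec.serum_k_mmol_l is not None and rec.serum_k_mmol_l < 2.8)
            or rec.rifle_level >= RifleLevel.RISK
        )
        if contra:
            continue
        prev = records.get(d - 1)
        compliant = rec.diuretics_given or rec.ultrafiltration_ml > 0
        if not compliant and prev is not None and prev.intake_ml > 0:
            compliant = rec.intake_ml <= 0.70 * prev.intake_ml
        if not compliant:
            n_dev += 1
    n_window = len(window)
    raw = 100.0 * (1.0 - n_dev / n_window)
    weigh_prop = n_weighed / n_window
    return n_dev, n_over, n_window, n_weighed, raw, weigh_prop, raw * weigh_prop


def assert_close(a, b, tol=1e-12):
    assert math.isclose(a, b, rel_tol=0, abs_tol=tol), f"{a} != {b}"
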