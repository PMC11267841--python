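"""Seeded generator of synthetic ICU cohorts for the fluid-balance pipeline.

No patient-level data from the trial are available, so every stage of
the pipeline is exercised on simulated cohorts whose statistical
structure matches what the scoring assumes: 12 ICUs crossing from a
control to an intervention period, per-arm weighing and adherence
propensities, day-indexed weight trajectories driven by a fluid-balance
drift, contraindication and hypotension episodes, and negative-binomial
lengths of stay truncated to >= 3 days (patients enter the cohort in
the post-acute phase, beyond 48 h after admission).

Weight dynamics are a deliberately minimal random walk, not a
physiological fluid-balance model: the true weight drifts up by
``overload_drift_kg_per_day`` on days following no compliant response
and down by the same amount after one.  Measured weights add Gaussian
noise.  Responses (intake restriction / diuretics / ultrafiltration,
mixed 0.6/0.3/0.1 by default) are only drawn on days where the overload
is *actionable*: the patient was weighed, the measured weight exceeded
the day's threshold, and no contraindication was drawn.  Contamination
in the control arm is modelled purely by that arm's higher-than-weekly
weighing and non-zero adherence propensities.

Determinism: each stay draws from an independent stream spawned from
``(seed, arm index, patient index)``, so enlarging one arm never
perturbs any other patient.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .data_model import (
    PatientDayRecord,
    PatientStay,
    Period,
    RifleLevel,
    ScoringRules,
)
from .scoring import day_threshold

__all__ = [
    "ArmConfig",
    "CohortConfig",
    "simulate_stay",
    "simulate_cohort",
    "simulate_overload_cohort",
    "default_trial_config",
]

_RESPONSES = ("restriction", "diuretics", "ultrafiltration")
_CONTRA_KINDS = ("hypotension", "sodium", "potassium", "rifle")


class ArmConfig(BaseModel):
    """Generator parameters for one (ICU, period) arm."""

    icu_id: str
    period: Period
    n_patients: int = Field(ge=1)
    n_expected: int = Field(ge=1, description="planned enrolment, for reach")
    p_weigh: float = Field(ge=0.0, le=1.0)
    p_adhere: float = Field(ge=0.0, le=1.0)
    p_contra: float = Field(default=0.10, ge=0.0, le=1.0)
    p_hypo_day: float = Field(default=0.12, ge=0.0, le=1.0)
    los_mean: float = Field(default=10.0, gt=0.0)
    los_dispersion: float = Field(default=4.0, gt=0.0)
    admission_weight_mean_kg: float = Field(default=75.0, gt=0.0)
    admission_weight_sd_kg: float = Field(default=15.0, ge=0.0)
    baseline_intake_ml: float = Field(default=2000.0, gt=0.0)
    overload_drift_kg_per_day: float = 0.4
    weight_noise_sd_kg: float = Field(default=0.3, ge=0.0)
    response_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)

    @model_validator(mode="after")
    def _check(self) -> "ArmConfig":
        if abs(sum(self.response_mix) - 1.0) > 1e-9:
            raise ValueError("response_mix must sum to 1")
        return self


class CohortConfig(BaseModel):
    """A full simulated trial: one :class:`ArmConfig` per (ICU, period)."""

    arms: list[ArmConfig]
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        keys = [(a.icu_id, a.period) for a in self.arms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (icu_id, period) arm")
        return self


def _truncated_nbinom_los(arm: ArmConfig, rng: np.random.Generator) -> int:
    # mean m, dispersion k  ->  nbinom(n=k, p=k/(k+m)); resample until >= 3
    k = arm.los_dispersion
    p = k / (k + arm.los_mean)
    while True:
        los = int(rng.negative_binomial(k, p))
        if los >= 3:
            return los


def _normal_labs(rng: np.random.Generator) -> tuple[float, float, RifleLevel]:
    na = float(rng.uniform(135.0, 148.0))
    kal = float(rng.uniform(3.2, 4.8))
    return na, kal, RifleLevel.NONE


def simulate_stay(
    arm: ArmConfig,
    patient_id: str,
    rng: np.random.Generator,
    rules: ScoringRules | None = None,
) -> PatientStay:
    """Simulate one stay from an explicit random stream.

    Day 1 is always weighed (admission weigh-in); subsequent days with
    probability ``p_weigh``.  Responses are drawn only on actionable
    in-window overload days and take effect on the next day's true
    weight.  Discharge weight is the last simulated true weight.
    """
    rules = rules or ScoringRules()
    los = _truncated_nbinom_los(arm, rng)
    admission = max(40.0, float(rng.normal(arm.admission_weight_mean_kg, arm.admission_weight_sd_kg)))

    records: list[PatientDayRecord] = []
    true_weight = admission
    prev_response = False
    prev_intake: float | None = None
    drift = arm.overload_drift_kg_per_day

    for d in range(1, los + 1):
        if d > 1:
            true_weight += -drift if prev_response else drift
        weighed = d == 1 or rng.random() < arm.p_weigh
        measured = (
            round(true_weight + float(rng.normal(0.0, arm.weight_noise_sd_kg)), 2)
            if weighed
            else None
        )

        contra = rng.random() < arm.p_contra
        contra_kind = _CONTRA_KINDS[int(rng.integers(len(_CONTRA_KINDS)))] if contra else None
        na, kal, rifle = _normal_labs(rng)
        if contra_kind == "sodium":
            na = float(rng.uniform(156.0, 165.0))
        elif contra_kind == "potassium":
            kal = float(rng.uniform(2.0, 2.7))
        elif contra_kind == "rifle":
            rifle = RifleLevel(int(rng.integers(RifleLevel.RISK, RifleLevel.FAILURE + 1)))
        hypotension = contra_kind == "hypotension" or rng.random() < arm.p_hypo_day

        response: str | None = None
        in_window = rules.window_start_day <= d <= rules.window_end_day
        if in_window and measured is not None and not contra:
            threshold = day_threshold(d, admission, rules)
            if measured > threshold and rng.random() < arm.p_adhere:
                response = _RESPONSES[int(rng.choice(3, p=arm.response_mix))]

        if response == "restriction" and prev_intake is not None and prev_intake > 0:
            # cut below the compliance boundary (<= 70 % of the previous day)
            intake = round(0.65 * prev_intake, 1)
        else:
            intake = round(arm.baseline_intake_ml * float(rng.uniform(0.9, 1.1)), 1)

        records.append(
            PatientDayRecord(
                patient_id=patient_id,
                icu_id=arm.icu_id,
                period=arm.period,
                day_index=d,
                weight_kg=measured,
                intake_ml=intake,
                diuretics_given=response == "diuretics",
                ultrafiltration_ml=1500.0 if response == "ultrafiltration" else 0.0,
                serum_na_mmol_l=round(na, 1),
                serum_k_mmol_l=round(kal, 2),
                rifle_level=rifle,
                hypotension=hypotension,
            )
        )
        prev_intake = intake
        prev_response = response is not None

    stay = PatientStay(
        patient_id=patient_id,
        icu_id=arm.icu_id,
        period=arm.period,
        admission_weight_kg=round(admission, 2),
        discharge_weight_kg=round(true_weight, 2),
        los_days=los,
        days=records,
    )
    stay.validate()
    return stay


def simulate_cohort(
    config: CohortConfig, rules: ScoringRules | None = None
) -> list[PatientStay]:
    """Simulate every arm of the cohort; byte-reproducible given the seed."""
    rules = rules or ScoringRules()
    stays: list[PatientStay] = []
    for arm_idx, arm in enumerate(config.arms):
        tag = "c" if arm.period is Period.CONTROL else "i"
        for patient_idx in range(arm.n_patients):
            ss = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(arm_idx, patient_idx)
            )
            rng = np.random.default_rng(ss)
            pid = f"{arm.icu_id}-{tag}{patient_idx:03d}"
            stays.append(simulate_stay(arm, pid, rng, rules))
    return stays


def simulate_overload_cohort(
    p_weigh: float,
    p_adhere: float,
    n_patients: int,
    n_window_days: int = 400,
    seed: int = 0,
) -> tuple[list[PatientStay], ScoringRules]:
    """Degenerate stress cohort: every weighed day is overloaded.

    A harness for analytic checks of the score: no contraindications,
    weight forced just above the day's threshold whenever weighed, and a
    diuretics response drawn with probability ``p_adhere`` on each
    weighed day.  Each deviation and weigh-in is then an independent
    Bernoulli draw, so the mean final score converges (as the window
    grows) to ``100 * (1 - p_weigh * (1 - p_adhere)) * p_weigh``.  The
    long default window keeps the finite-window covariance between the
    deviation rate and the weigh-in proportion, of order 1/window
    length, well below Monte-Carlo resolution.

    Returns the stays together with the widened :class:`ScoringRules`
    to score them with.
    """
    if not 0.0 <= p_weigh <= 1.0 or not 0.0 <= p_adhere <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    window_end = 1 + n_window_days
    rules = ScoringRules(window_end_day=window_end, late_band=(8, window_end))
    admission = 70.0
    stays: list[PatientStay] = []
    for patient_idx in range(n_patients):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(0, patient_idx))
        rng = np.random.default_rng(ss)
        records = []
        for d in range(1, window_end + 1):
            weighed = d == 1 or rng.random() < p_weigh
            if weighed and d >= rules.window_start_day:
                weight = day_threshold(d, admission, rules) + 1.0
            elif weighed:
                weight = admission
            else:
                weight = None
            respond = weighed and d >= rules.window_start_day and rng.random() < p_adhere
            records.append(
                PatientDayRecord(
                    patient_id=f"p{patient_idx:04d}",
                    icu_id="stress",
                    period=Period.INTERVENTION,
                    day_index=d,
                    weight_kg=weight,
                    intake_ml=2000.0,
                    diuretics_given=respond,
                    ultrafiltration_ml=0.0,
                    serum_na_mmol_l=140.0,
                    serum_k_mmol_l=4.0,
                    rifle_level=RifleLevel.NONE,
                    hypotension=False,
                )
            )
        stays.append(
            PatientStay(
                patient_id=f"p{patient_idx:04d}",
                icu_id="stress",
                period=Period.INTERVENTION,
                admission_weight_kg=admission,
                discharge_weight_kg=None,
                los_days=window_end,
                days=records,
            )
        )
    return stays, rules


# Default calibration: 12 ICUs (A-L) x 2 periods.  Planned enrolment is 60
# patients per ICU per period; realised sizes, weighing propensities and
# adherence levels vary widely across ICUs in the control period (weekly
# standard of care, habit-driven contamination) and sit uniformly higher in
# the intervention period (daily-weighing protocol, imperfect fidelity).
_DEFAULT_ARMS: Sequence[tuple[str, int, int, float, float, float, float]] = [
    # icu, n_control, n_intervention, p_weigh_c, p_adhere_c, p_weigh_i, p_adhere_i
    ("A", 86, 47, 0.67, 0.60, 0.71, 0.85),
    ("B", 91, 86, 0.54, 0.65, 0.81, 0.92),
    ("C", 52, 49, 0.24, 0.30, 0.75, 0.80),
    ("D", 35, 29, 0.54, 0.65, 0.71, 0.65),
    ("E", 44, 59, 0.32, 0.40, 0.83, 0.92),
    ("F", 104, 58, 0.46, 0.45, 0.63, 0.70),
    ("G", 44, 49, 0.70, 0.70, 0.78, 0.85),
    ("H", 35, 25, 0.24, 0.35, 0.83, 0.97),
    ("I", 61, 57, 0.43, 0.50, 0.75, 0.85),
    ("J", 71, 71, 0.65, 0.70, 0.76, 0.85),
    ("K", 49, 65, 0.56, 0.60, 0.70, 0.85),
    ("L", 46, 48, 0.27, 0.40, 0.65, 0.90),
]


def default_trial_config(seed: int = 0) -> CohortConfig:
    """The default 12-ICU, two-period cohort configuration."""
    arms = []
    for icu, n_c, n_i, pw_c, pa_c, pw_i, pa_i in _DEFAULT_ARMS:
        arms.append(
            ArmConfig(
                icu_id=icu,
                period=Period.CONTROL,
                n_patients=n_c,
                n_expected=60,
                p_weigh=pw_c,
                p_adhere=pa_c,
            )
        )
        arms.append(
            ArmConfig(
                icu_id=icu,
                period=Period.INTERVENTION,
                n_patients=n_i,
                n_expected=60,
                p_weigh=pw_i,
                p_adhere=pa_i,
            )
        )
    return CohortConfig(arms=arms, seed=seed)
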