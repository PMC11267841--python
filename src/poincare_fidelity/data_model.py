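"""Domain types, tabular I/O and validation for ICU fluid-balance cohorts.

The pipeline works on two long-format tables:

``stays.csv``
    one row per patient: admission weight, discharge weight, length of
    stay, ICU and trial period.

``patient_days.csv``
    one row per patient per ICU day: measured weight (absent when the
    patient was not weighed), fluid intake volume, treatments
    (diuretics, ultrafiltration), serum sodium/potassium, RIFLE renal
    dysfunction level and an arterial-hypotension flag.

Day indices are 1-based integers with Day 1 = the calendar day of ICU
admission; no dates or timezones are handled.  A missing weight cell is
loaded as absent (``None``), never as zero — a zero weight would
silently read as "no fluid overload".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, model_validator

__all__ = [
    "Period",
    "RifleLevel",
    "PatientDayRecord",
    "PatientStay",
    "ScoringRules",
    "ExposureResult",
    "IcuPeriodSummary",
    "SchemaError",
    "IntegrityError",
    "CohortValidationError",
    "read_patient_days",
    "write_cohort",
    "write_summary_table",
    "read_summary_table",
    "DAY_COLUMNS",
    "STAY_COLUMNS",
]


class SchemaError(ValueError):
    """A mandatory column is missing or unmappable."""


class IntegrityError(ValueError):
    """Duplicate keys or cross-table inconsistencies."""


class CohortValidationError(ValueError):
    """A row violates a declared domain invariant."""


class Period(str, enum.Enum):
    """Trial period of a stepped-wedge cluster: usual care vs strategy."""

    CONTROL = "control"
    INTERVENTION = "intervention"


class RifleLevel(enum.IntEnum):
    """Ordered RIFLE staging of renal dysfunction (none < risk < ... < eskd)."""

    NONE = 0
    RISK = 1
    INJURY = 2
    FAILURE = 3
    LOSS = 4
    ESKD = 5

    @classmethod
    def from_name(cls, name: str) -> "RifleLevel":
        try:
            return cls[str(name).strip().upper()]
        except KeyError:
            raise CohortValidationError(f"unknown RIFLE level: {name!r}") from None


@dataclass(slots=True)
class PatientDayRecord:
    """One ICU day for one patient.

    ``weight_kg is None`` means the patient was not weighed that day.
    ``intake_ml`` is the oral plus parenteral volume, excluding vascular
    filling.  Absent labs are ``None`` and never trigger a
    contraindication.
    """

    patient_id: str
    icu_id: str
    period: Period
    day_index: int
    weight_kg: float | None
    intake_ml: float
    diuretics_given: bool
    ultrafiltration_ml: float
    serum_na_mmol_l: float | None
    serum_k_mmol_l: float | None
    rifle_level: RifleLevel
    hypotension: bool

    def validate(self) -> None:
        if self.day_index < 1:
            raise CohortValidationError(
                f"{self.patient_id}: day_index must be >= 1, got {self.day_index}"
            )
        for name in ("weight_kg", "intake_ml", "ultrafiltration_ml"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise CohortValidationError(
                    f"{self.patient_id} day {self.day_index}: {name} < 0"
                )
        for name in ("serum_na_mmol_l", "serum_k_mmol_l"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise CohortValidationError(
                    f"{self.patient_id} day {self.day_index}: {name} must be > 0"
                )


@dataclass(slots=True)
class PatientStay:
    """A patient's admission-level facts plus their ordered day records."""

    patient_id: str
    icu_id: str
    period: Period
    admission_weight_kg: float
    discharge_weight_kg: float | None
    los_days: int
    days: list[PatientDayRecord] = field(default_factory=list)

    def validate(self) -> None:
        if self.los_days < 1:
            raise CohortValidationError(f"{self.patient_id}: los_days must be >= 1")
        if self.admission_weight_kg <= 0:
            raise CohortValidationError(
                f"{self.patient_id}: admission weight must be > 0"
            )
        seen: set[int] = set()
        prev = 0
        for rec in self.days:
            rec.validate()
            if rec.day_index in seen:
                raise IntegrityError(
                    f"{self.patient_id}: duplicate day_index {rec.day_index}"
                )
            if rec.day_index < prev:
                raise CohortValidationError(
                    f"{self.patient_id}: day records not sorted ascending"
                )
            if (rec.patient_id, rec.icu_id, rec.period) != (
                self.patient_id,
                self.icu_id,
                self.period,
            ):
                raise IntegrityError(
                    f"{self.patient_id}: day {rec.day_index} carries foreign "
                    "patient/icu/period identifiers"
                )
            seen.add(rec.day_index)
            prev = rec.day_index
        if self.days and self.days[-1].day_index > self.los_days:
            raise CohortValidationError(
                f"{self.patient_id}: day_index {self.days[-1].day_index} "
                f"exceeds los_days {self.los_days}"
            )

    def day(self, day_index: int) -> PatientDayRecord | None:
        for rec in self.days:
            if rec.day_index == day_index:
                return rec
        return None


class ScoringRules(BaseModel):
    """Every numeric constant of the exposure score.

    The overload threshold is day-indexed relative to admission weight:
    admission + 2 kg on Day 2, admission weight on Days 3-7, admission
    − 2 kg on Days 8-14.  A compliant response to overload is a >= 30 %
    intake restriction versus the previous day, diuretics, or
    ultrafiltration.  Restriction is contraindicated by hypotension,
    Na > 155 mmol/L, K < 2.8 mmol/L, or RIFLE >= risk; on such days no
    deviation is counted.

    ``denominator`` selects the raw-score denominator: ``"window"``
    (days of the stay inside the Day 2-14 window; default) or
    ``"full_los"`` (total length of stay).
    """

    window_start_day: int = 2
    window_end_day: int = 14
    early_offset_kg: float = 2.0
    mid_offset_kg: float = 0.0
    late_offset_kg: float = -2.0
    mid_band: tuple[int, int] = (3, 7)
    late_band: tuple[int, int] = (8, 14)
    restriction_fraction: float = 0.30
    na_max_mmol_l: float = 155.0
    k_min_mmol_l: float = 2.8
    rifle_contraindication_min: RifleLevel = RifleLevel.RISK
    denominator: str = "window"
    # control arm expects one weigh-in per started 7-day block (weekly
    # standard of care); intervention expects one per in-window day
    control_expected_block_days: int = 7

    @model_validator(mode="after")
    def _check(self) -> "ScoringRules":
        if not self.window_start_day < self.window_end_day:
            raise ValueError("window_start_day must be < window_end_day")
        if not 0 < self.restriction_fraction < 1:
            raise ValueError("restriction_fraction must lie in (0, 1)")
        if self.mid_band[0] != self.window_start_day + 1:
            raise ValueError("mid band must start the day after the early day")
        if self.late_band != (self.mid_band[1] + 1, self.window_end_day):
            raise ValueError("bands must tile the scoring window")
        if self.denominator not in ("window", "full_los"):
            raise ValueError("denominator must be 'window' or 'full_los'")
        return self


@dataclass(slots=True)
class ExposureResult:
    """Per-patient decomposition of the exposure score.

    ``final_score = raw_score * weigh_proportion``; both scores live on
    a 0-100 scale where 100 means maximal delivered dose of the
    strategy.
    """

    patient_id: str
    icu_id: str
    period: Period
    n_window_days: int
    n_weighed_window: int
    weigh_proportion: float
    n_overload_days: int
    n_deviations: int
    raw_score: float
    final_score: float

    def validate(self) -> None:
        if not (
            self.n_deviations
            <= self.n_overload_days
            <= self.n_weighed_window
            <= self.n_window_days
        ):
            raise CohortValidationError(
                f"{self.patient_id}: counter ordering violated"
            )
        if not math.isclose(
            self.final_score, self.raw_score * self.weigh_proportion, abs_tol=1e-9
        ):
            raise CohortValidationError(
                f"{self.patient_id}: final_score != raw_score * weigh_proportion"
            )


@dataclass(slots=True)
class IcuPeriodSummary:
    """One summary row per (ICU, period): reach, dose/fidelity, mechanisms.

    ``weighing_achieved_expected_pct`` may exceed 100 in the control
    period, where the expectation is the weekly standard of care.
    Standard deviations are ``None`` for single-patient groups.
    """

    icu_id: str
    period: Period
    n_patients: int
    reach_pct: float | None
    weekly_weighins_mean: float
    weekly_weighins_sd: float | None
    weighing_achieved_expected_pct: float
    score_mean: float
    score_sd: float | None
    hypotension_pct: float
    hypotension_n: int
    weight_change_mean_kg: float | None
    weight_change_sd_kg: float | None


# ---------------------------------------------------------------------------
# Tabular I/O

DAY_COLUMNS = [
    "patient_id",
    "icu_id",
    "period",
    "day_index",
    "weight_kg",
    "intake_ml",
    "diuretics_given",
    "ultrafiltration_ml",
    "serum_na_mmol_l",
    "serum_k_mmol_l",
    "rifle_level",
    "hypotension",
]

STAY_COLUMNS = [
    "patient_id",
    "icu_id",
    "period",
    "admission_weight_kg",
    "discharge_weight_kg",
    "los_days",
]

SUMMARY_COLUMNS = [
    "icu_id",
    "period",
    "n_patients",
    "reach_pct",
    "weekly_weighins_mean",
    "weekly_weighins_sd",
    "weighing_achieved_expected_pct",
    "score_mean",
    "score_sd",
    "hypotension_pct",
    "hypotension_n",
    "weight_change_mean_kg",
    "weight_change_sd_kg",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _as_bool(value, where: str) -> bool:
    if isinstance(value, bool):
        return value
    if value in (0, 1):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise CohortValidationError(f"{where}: cannot interpret {value!r} as boolean")


def read_patient_days(
    days_path: str | Path,
    stays_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
) -> list[PatientStay]:
    """Read a cohort from delimited text into validated :class:`PatientStay`.

    Parameters
    ----------
    days_path
        CSV with one row per patient-day, header naming every
        :class:`PatientDayRecord` field.  When ``stays_path`` is omitted
        the file must additionally carry ``admission_weight_kg`` and
        ``los_days`` columns (repeated per row), and optionally
        ``discharge_weight_kg``.
    stays_path
        Optional stay-level CSV (one row per patient) carrying the
        admission-level columns.
    schema
        Optional mapping from canonical field names to the column names
        used in the file(s).

    Empty weight/lab cells become absent values, never zero.  Duplicate
    ``(patient_id, day_index)`` pairs raise :class:`IntegrityError`;
    negative volumes raise :class:`CohortValidationError` naming the row.
    """
    schema = dict(schema or {})

    def col(name: str) -> str:
        return schema.get(name, name)

    days = pd.read_csv(days_path, comment="#")
    _require_columns(days, [col(c) for c in DAY_COLUMNS], str(days_path))

    if stays_path is not None:
        stays_df = pd.read_csv(stays_path, comment="#")
        _require_columns(stays_df, [col(c) for c in STAY_COLUMNS], str(stays_path))
        if stays_df[col("patient_id")].duplicated().any():
            dup = stays_df[col("patient_id")][stays_df[col("patient_id")].duplicated()].iloc[0]
            raise IntegrityError(f"{stays_path}: duplicate patient_id {dup!r}")
    else:
        for extra in ("admission_weight_kg", "los_days"):
            if col(extra) not in days.columns:
                raise SchemaError(
                    f"{days_path}: missing mandatory column(s): {col(extra)}"
                )
        stays_df = days.drop_duplicates(subset=col("patient_id"))

    stay_meta: dict[str, dict] = {}
    for _, row in stays_df.iterrows():
        pid = str(row[col("patient_id")])
        stay_meta[pid] = {
            "icu_id": str(row[col("icu_id")]),
            "period": Period(str(row[col("period")])),
            "admission_weight_kg": float(row[col("admission_weight_kg")]),
            "discharge_weight_kg": _opt_float(row.get(col("discharge_weight_kg"))),
            "los_days": int(row[col("los_days")]),
        }

    grouped: dict[str, list[PatientDayRecord]] = {pid: [] for pid in stay_meta}
    seen_days: set[tuple[str, int]] = set()
    for i, row in days.iterrows():
        pid = str(row[col("patient_id")])
        if pid not in stay_meta:
            raise IntegrityError(
                f"{days_path} row {i}: patient {pid!r} has day rows but no stay row"
            )
        day_index = int(row[col("day_index")])
        if (pid, day_index) in seen_days:
            raise IntegrityError(
                f"{days_path} row {i}: duplicate (patient_id, day_index) "
                f"({pid}, {day_index})"
            )
        seen_days.add((pid, day_index))
        rec = PatientDayRecord(
            patient_id=pid,
            icu_id=str(row[col("icu_id")]),
            period=Period(str(row[col("period")])),
            day_index=day_index,
            weight_kg=_opt_float(row[col("weight_kg")]),
            intake_ml=float(row[col("intake_ml")]),
            diuretics_given=_as_bool(row[col("diuretics_given")], f"row {i}"),
            ultrafiltration_ml=float(row[col("ultrafiltration_ml")]),
            serum_na_mmol_l=_opt_float(row[col("serum_na_mmol_l")]),
            serum_k_mmol_l=_opt_float(row[col("serum_k_mmol_l")]),
            rifle_level=RifleLevel.from_name(row[col("rifle_level")]),
            hypotension=_as_bool(row[col("hypotension")], f"row {i}"),
        )
        try:
            rec.validate()
        except CohortValidationError as exc:
            raise CohortValidationError(f"{days_path} row {i}: {exc}") from None
        grouped[pid].append(rec)

    stays: list[PatientStay] = []
    for pid, meta in stay_meta.items():
        recs = sorted(grouped[pid], key=lambda r: r.day_index)
        stay = PatientStay(patient_id=pid, days=recs, **meta)
        stay.validate()
        stays.append(stay)
    return stays


def _write_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_cohort(
    stays: Iterable[PatientStay],
    stays_path: str | Path,
    days_path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a cohort as ``stays.csv`` + ``patient_days.csv`` (UTF-8 CSV)."""
    stays = list(stays)
    stay_rows = []
    day_rows = []
    for stay in stays:
        stay_rows.append(
            {
                "patient_id": stay.patient_id,
                "icu_id": stay.icu_id,
                "period": stay.period.value,
                "admission_weight_kg": stay.admission_weight_kg,
                "discharge_weight_kg": stay.discharge_weight_kg,
                "los_days": stay.los_days,
            }
        )
        for rec in stay.days:
            day_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "icu_id": rec.icu_id,
                    "period": rec.period.value,
                    "day_index": rec.day_index,
                    "weight_kg": rec.weight_kg,
                    "intake_ml": rec.intake_ml,
                    "diuretics_given": int(rec.diuretics_given),
                    "ultrafiltration_ml": rec.ultrafiltration_ml,
                    "serum_na_mmol_l": rec.serum_na_mmol_l,
                    "serum_k_mmol_l": rec.serum_k_mmol_l,
                    "rifle_level": rec.rifle_level.name.lower(),
                    "hypotension": int(rec.hypotension),
                }
            )
    _write_csv(pd.DataFrame(stay_rows, columns=STAY_COLUMNS), stays_path, header_comment)
    _write_csv(pd.DataFrame(day_rows, columns=DAY_COLUMNS), days_path, header_comment)


def write_summary_table(
    rows: Iterable[IcuPeriodSummary],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write one row per (ICU, period); round-trips losslessly through
    :func:`read_summary_table`."""
    rows = list(rows)
    if not rows:
        raise ValueError("summary table must not be empty")
    keys = [(r.icu_id, r.period) for r in rows]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise IntegrityError(f"duplicate (icu_id, period): {dup}")
    df = pd.DataFrame(
        [
            {
                "icu_id": r.icu_id,
                "period": r.period.value,
                "n_patients": r.n_patients,
                "reach_pct": r.reach_pct,
                "weekly_weighins_mean": r.weekly_weighins_mean,
                "weekly_weighins_sd": r.weekly_weighins_sd,
                "weighing_achieved_expected_pct": r.weighing_achieved_expected_pct,
                "score_mean": r.score_mean,
                "score_sd": r.score_sd,
                "hypotension_pct": r.hypotension_pct,
                "hypotension_n": r.hypotension_n,
                "weight_change_mean_kg": r.weight_change_mean_kg,
                "weight_change_sd_kg": r.weight_change_sd_kg,
            }
            for r in rows
        ],
        columns=SUMMARY_COLUMNS,
    )
    _write_csv(df, path, header_comment)


def read_summary_table(path: str | Path) -> list[IcuPeriodSummary]:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, SUMMARY_COLUMNS, str(path))
    out = []
    for _, row in df.iterrows():
        out.append(
            IcuPeriodSummary(
                icu_id=str(row["icu_id"]),
                period=Period(row["period"]),
                n_patients=int(row["n_patients"]),
                reach_pct=_opt_float(row["reach_pct"]),
                weekly_weighins_mean=float(row["weekly_weighins_mean"]),
                weekly_weighins_sd=_opt_float(row["weekly_weighins_sd"]),
                weighing_achieved_expected_pct=float(
                    row["weighing_achieved_expected_pct"]
                ),
                score_mean=float(row["score_mean"]),
                score_sd=_opt_float(row["score_sd"]),
                hypotension_pct=float(row["hypotension_pct"]),
                hypotension_n=int(row["hypotension_n"]),
                weight_change_mean_kg=_opt_float(row["weight_change_mean_kg"]),
                weight_change_sd_kg=_opt_float(row["weight_change_sd_kg"]),
            )
        )
    return out
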