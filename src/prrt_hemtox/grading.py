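"""CTCAE v5 grading of longitudinal haematology panels during PRRT.

Four laboratory lines are graded: haemoglobin (anaemia), leucocytes
(white-blood-cell decrease), neutrophils and platelets.  Grading is purely
value-based: a value at or above the lower limit of normal (LLN) is grade 0,
and successively lower half-open bins give grades 1..4 (anaemia caps at
grade 3 because its grade 4 is a clinical, not numeric, criterion).

A patient's overall toxicity is the highest grade reached by any parameter
at any time after the first administration; the cohort is partitioned into
the grade groups 0-1, 2 and 3-4 on that basis.
"""

from __future__ import annotations

import importlib.resources
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETERS",
    "GradingRules",
    "LabSeries",
    "TreatmentCourse",
    "AdjustmentFlags",
    "GradeProfile",
    "load_default_rules",
    "grade_value",
    "nadir",
    "overall_patient_grade",
    "per_cycle_grades",
    "eligibility_check",
    "classify_course",
    "grade_profile",
    "grade_group",
    "labs_to_frame",
    "labs_from_frame",
    "courses_to_frame",
    "courses_from_frame",
]

PARAMETERS = ("haemoglobin", "leucocytes", "neutrophils", "platelets")

_PARAM_ALIASES = {
    "haemoglobin": "haemoglobin",
    "hemoglobin": "haemoglobin",
    "hgb": "haemoglobin",
    "hb": "haemoglobin",
    "leucocytes": "leucocytes",
    "leukocytes": "leucocytes",
    "wbc": "leucocytes",
    "neutrophils": "neutrophils",
    "anc": "neutrophils",
    "platelets": "platelets",
    "plt": "platelets",
}

_COUNT_UNITS = {"1e9/l", "10^9/l", "x10^9/l", "×10^9/l", "10e9/l", "giga/l"}

DEFAULT_OBSERVATION_TAIL_DAYS = 70  # observation ends 10 weeks after the last cycle


def canonical_parameter(name: str) -> str:
    try:
        return _PARAM_ALIASES[name.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown laboratory parameter {name!r}") from None


@dataclass
class GradingRules:
    """Numeric CTCAE grade bins in canonical units (g/dL, 1e9/L).

    ``grade_upper_bounds[p]`` lists, per parameter, the exclusive upper
    bounds of grades 2, 3, ... (grade 1 spans [first bound, LLN)); a value
    >= LLN is grade 0.  ``hgb_conversion`` converts haemoglobin mmol/L to
    g/dL (1.6113, the monomeric-Fe convention of Dutch laboratories).
    """

    grade_upper_bounds: dict[str, list[float]]
    lln: dict[str, float | dict[str, float]]
    max_grade: dict[str, int]
    hgb_conversion: float = 1.6113

    @classmethod
    def from_dict(cls, d: dict) -> "GradingRules":
        pars = d["parameters"]
        return cls(
            grade_upper_bounds={p: list(map(float, v["grade_upper_bounds"])) for p, v in pars.items()},
            lln={p: v["lln"] for p, v in pars.items()},
            max_grade={p: int(v["max_grade"]) for p, v in pars.items()},
            hgb_conversion=float(d.get("haemoglobin_gdl_per_mmoll", 1.6113)),
        )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GradingRules":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def lln_for(self, parameter: str, sex: str | None = None) -> float:
        lln = self.lln[parameter]
        if isinstance(lln, dict):
            key = (sex or "female").lower()
            if key not in lln:
                raise ValueError(f"no LLN for sex {sex!r} in parameter {parameter!r}")
            return float(lln[key])
        return float(lln)


def load_default_rules() -> GradingRules:
    ref = importlib.resources.files("prrt_hemtox").joinpath("data/ctcae_v5.json")
    return GradingRules.from_dict(json.loads(ref.read_text()))


def to_canonical(parameter: str, value: float, unit: str, rules: GradingRules) -> float:
    """Convert a lab value to the canonical grading unit."""
    parameter = canonical_parameter(parameter)
    u = unit.strip().lower()
    if parameter == "haemoglobin":
        if u == "mmol/l":
            return value * rules.hgb_conversion
        if u == "g/dl":
            return value
        raise ValueError(f"unknown haemoglobin unit {unit!r} (use mmol/L or g/dL)")
    if u in _COUNT_UNITS:
        return value
    raise ValueError(f"unknown unit {unit!r} for {parameter} (counts are in 1e9/L)")


def grade_value(
    parameter: str,
    value: float,
    unit: str,
    rules: GradingRules | None = None,
    sex: str | None = None,
) -> int:
    """CTCAE grade (0-4) of one laboratory value.

    Only the grade-0/1 boundary depends on the LLN (and, for haemoglobin,
    on sex); the grade >= 2 boundaries are absolute.
    """
    rules = rules or load_default_rules()
    parameter = canonical_parameter(parameter)
    if value <= 0:
        raise ValueError(f"{parameter} value must be positive, got {value}")
    v = to_canonical(parameter, value, unit, rules)
    if v >= rules.lln_for(parameter, sex):
        return 0
    grade = 1
    for bound in rules.grade_upper_bounds[parameter]:
        if v < bound:
            grade += 1
    return min(grade, rules.max_grade[parameter])


def grade_group(grade: int) -> str:
    """Partition {0..4} into the reporting groups 0-1 / 2 / 3-4."""
    if grade <= 1:
        return "0-1"
    if grade == 2:
        return "2"
    return "3-4"


# ---------------------------------------------------------------------------
# longitudinal containers


@dataclass
class LabSeries:
    """Timestamped lab values of one patient, days relative to first cycle.

    ``records[parameter]`` is a list of ``(day, value, unit)``; exactly one
    baseline record (day <= 0) per parameter is expected.
    """

    patient_id: str
    records: dict[str, list[tuple[float, float, str]]]
    sex: str = "female"

    def __post_init__(self) -> None:
        clean: dict[str, list[tuple[float, float, str]]] = {}
        for p, recs in self.records.items():
            p = canonical_parameter(p)
            recs = sorted(((float(d), float(v), u) for d, v, u in recs), key=lambda r: r[0])
            if any(v <= 0 for _, v, _ in recs):
                raise ValueError(f"{self.patient_id}/{p}: lab values must be positive")
            n_base = sum(1 for d, _, _ in recs if d <= 0)
            if recs and n_base != 1:
                raise ValueError(f"{self.patient_id}/{p}: expected exactly one baseline record (day <= 0), got {n_base}")
            clean[p] = recs
        self.records = clean

    def baseline(self, parameter: str) -> tuple[float, float, str]:
        parameter = canonical_parameter(parameter)
        for d, v, u in self.records[parameter]:
            if d <= 0:
                return d, v, u
        raise ValueError(f"{self.patient_id}/{parameter}: no baseline record")


@dataclass
class TreatmentCourse:
    """Administered PRRT cycles of one patient.

    ``cycles`` lists ``(cycle_index, day, activity_GBq)`` with strictly
    increasing days and positive activities; up to four cycles are planned.
    """

    patient_id: str
    cycles: list[tuple[int, float, float]]
    discontinuation_reason: str = "none"
    max_cycles: int = 4

    def __post_init__(self) -> None:
        self.cycles = sorted(((int(i), float(d), float(a)) for i, d, a in self.cycles), key=lambda c: c[1])
        days = [d for _, d, _ in self.cycles]
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ValueError(f"{self.patient_id}: cycle days must be strictly increasing")
        if any(a <= 0 for _, _, a in self.cycles):
            raise ValueError(f"{self.patient_id}: administered activity must be positive")
        if len(self.cycles) > self.max_cycles:
            raise ValueError(f"{self.patient_id}: more than {self.max_cycles} cycles")

    @property
    def cycle_days(self) -> list[float]:
        return [d for _, d, _ in self.cycles]


# ---------------------------------------------------------------------------
# nadir and grading operations


def nadir(
    series: LabSeries,
    parameter: str,
    window: tuple[float, float | None] = (0.0, None),
) -> tuple[float, float]:
    """Lowest in-window value and its day (ties -> earliest day).

    The default window starts at day 0 and is open-ended; baseline records
    (day <= 0) are excluded from the nadir search.
    """
    parameter = canonical_parameter(parameter)
    start, end = window
    start = max(float(start), 0.0)
    obs = [
        (d, v)
        for d, v, _ in series.records.get(parameter, [])
        if d > start and (end is None or d <= end)
    ]
    if not obs:
        raise ValueError(f"{series.patient_id}/{parameter}: no observations in window ({start}, {end}]")
    best_v = min(v for _, v in obs)
    best_d = min(d for d, v in obs if v == best_v)
    return best_v, best_d


def _unit_of(series: LabSeries, parameter: str) -> str:
    return series.records[parameter][0][2]


def overall_patient_grade(
    series: LabSeries,
    rules: GradingRules | None = None,
    window: tuple[float, float | None] = (0.0, None),
) -> dict:
    """Per-parameter nadir grades and the overall (max) grade of one patient."""
    rules = rules or load_default_rules()
    missing = [p for p in PARAMETERS if not series.records.get(p)]
    if missing:
        raise ValueError(f"{series.patient_id}: missing parameters {missing}")
    per_param = {}
    for p in PARAMETERS:
        v, d = nadir(series, p, window)
        g = grade_value(p, v, _unit_of(series, p), rules, sex=series.sex)
        per_param[p] = {"nadir_value": v, "nadir_day": d, "grade": g}
    overall = max(info["grade"] for info in per_param.values())
    return {
        "patient_id": series.patient_id,
        "parameters": per_param,
        "overall_grade": overall,
        "grade_group": grade_group(overall),
    }


def per_cycle_grades(
    series: LabSeries,
    course: TreatmentCourse,
    rules: GradingRules | None = None,
    tail_days: float = DEFAULT_OBSERVATION_TAIL_DAYS,
) -> dict:
    """Highest grade per parameter in each cycle window.

    The window of cycle k is half-open ``(day_k, day_{k+1}]``; the last
    window extends ``tail_days`` (default 10 weeks) past the last
    administration.  Also reports, per grade level, the first cycle in
    which it was reached.
    """
    rules = rules or load_default_rules()
    if not course.cycles:
        raise ValueError(f"{course.patient_id}: course has no cycles")
    days = course.cycle_days
    windows = [(days[i], days[i + 1] if i + 1 < len(days) else days[-1] + tail_days) for i in range(len(days))]
    rows = []
    for (idx, _, _), (w0, w1) in zip(course.cycles, windows):
        row: dict = {"cycle": idx, "window_start": w0, "window_end": w1}
        grades = []
        for p in PARAMETERS:
            obs = [(d, v) for d, v, _ in series.records.get(p, []) if w0 < d <= w1]
            if obs:
                g = max(grade_value(p, v, _unit_of(series, p), rules, sex=series.sex) for _, v in obs)
            else:
                g = None
            row[p] = g
            if g is not None:
                grades.append(g)
        row["overall"] = max(grades) if grades else None
        rows.append(row)
    first_occurrence: dict[int, int] = {}
    for row in rows:
        if row["overall"] is None:
            continue
        for level in range(1, row["overall"] + 1):
            first_occurrence.setdefault(level, row["cycle"])
    return {"patient_id": series.patient_id, "cycles": rows, "first_occurrence": first_occurrence}


DEFAULT_ELIGIBILITY_LIMITS = {
    "haemoglobin_mmoll": 5.5,  # strict >
    "leucocytes": 3.0,  # strict >, 1e9/L
    "neutrophils": 1.0,  # strict >, 1e9/L
    "platelets": 75.0,  # strict >, 1e9/L
    "gfr": 50.0,  # strict >, mL/min/1.7m^2
    "albumin": 30.0,  # strict >, g/L
    "bilirubin_max_umoll": 51.0,  # pass if <= 3 x ULN (ULN 17 umol/L)
}


def eligibility_check(values: dict[str, float], limits: dict[str, float] | None = None) -> tuple[bool, list[str]]:
    """Screen baseline values against the PRRT inclusion thresholds.

    ``values`` must provide haemoglobin (mmol/L), leucocytes, neutrophils,
    platelets (1e9/L), gfr, albumin and bilirubin.  All count/function
    criteria are strict ``>`` (a boundary value fails); bilirubin passes at
    or below three times the upper limit of normal.  Returns the flag and
    the complete list of failed criteria.
    """
    limits = {**DEFAULT_ELIGIBILITY_LIMITS, **(limits or {})}
    required = ["haemoglobin", "leucocytes", "neutrophils", "platelets", "gfr", "albumin", "bilirubin"]
    missing = [k for k in required if k not in values]
    if missing:
        raise ValueError(f"missing eligibility inputs: {missing}")
    failing = []
    if not values["haemoglobin"] > limits["haemoglobin_mmoll"]:
        failing.append("haemoglobin")
    for key in ("leucocytes", "neutrophils", "platelets", "gfr", "albumin"):
        if not values[key] > limits[key]:
            failing.append(key)
    if not values["bilirubin"] <= limits["bilirubin_max_umoll"]:
        failing.append("bilirubin")
    return (not failing), failing


@dataclass
class AdjustmentFlags:
    """Observed deviations of a treatment course from the planned schedule."""

    patient_id: str
    postponed: bool
    postponed_intervals_days: list[float]
    reduced: bool
    reduced_activities_gbq: list[float]
    completed: bool
    discontinued_for_haematotoxicity: bool


def classify_course(
    course: TreatmentCourse,
    planned_interval_days: float = 70.0,
    planned_activity_gbq: float = 7.4,
    interval_tolerance_days: float = 7.0,
    activity_tolerance_gbq: float = 0.2,
    planned_cycles: int = 4,
) -> AdjustmentFlags:
    """Flag postponed cycles, reduced activities and non-completion.

    A cycle is postponed when the preceding interval exceeds the planned
    interval plus tolerance; an activity is reduced when it falls below the
    planned activity minus tolerance.  This describes the administered
    course; it does not model the clinical decision behind it.
    """
    if not course.cycles:
        raise ValueError(f"{course.patient_id}: course has no cycles")
    days = course.cycle_days
    intervals = [d2 - d1 for d1, d2 in zip(days, days[1:])]
    postponed_iv = [iv for iv in intervals if iv > planned_interval_days + interval_tolerance_days]
    reduced_act = [a for _, _, a in course.cycles if a < planned_activity_gbq - activity_tolerance_gbq]
    return AdjustmentFlags(
        patient_id=course.patient_id,
        postponed=bool(postponed_iv),
        postponed_intervals_days=postponed_iv,
        reduced=bool(reduced_act),
        reduced_activities_gbq=reduced_act,
        completed=len(course.cycles) == planned_cycles,
        discontinued_for_haematotoxicity=course.discontinuation_reason == "haematotoxicity",
    )


@dataclass
class GradeProfile:
    """Aggregated toxicity profile of one patient."""

    patient_id: str
    parameters: dict
    overall_grade: int
    grade_group: str
    per_cycle: dict
    flags: AdjustmentFlags
    eligible_at_baseline: bool | None = None
    failing_criteria: list[str] = field(default_factory=list)


def grade_profile(
    series: LabSeries,
    course: TreatmentCourse,
    rules: GradingRules | None = None,
    eligibility_values: dict[str, float] | None = None,
    tail_days: float = DEFAULT_OBSERVATION_TAIL_DAYS,
) -> GradeProfile:
    """Full grading of one patient: nadirs, per-cycle grades, course flags.

    The overall observation window runs from the first administration to
    ``tail_days`` after the last one.
    """
    rules = rules or load_default_rules()
    window = (0.0, course.cycle_days[-1] + tail_days if course.cycles else None)
    overall = overall_patient_grade(series, rules, window)
    cyc = per_cycle_grades(series, course, rules, tail_days)
    flags = classify_course(course)
    eligible = None
    failing: list[str] = []
    if eligibility_values is not None:
        eligible, failing = eligibility_check(eligibility_values)
    return GradeProfile(
        patient_id=series.patient_id,
        parameters=overall["parameters"],
        overall_grade=overall["overall_grade"],
        grade_group=overall["grade_group"],
        per_cycle=cyc,
        flags=flags,
        eligible_at_baseline=eligible,
        failing_criteria=failing,
    )


def profiles_to_frame(profiles: list[GradeProfile]) -> pd.DataFrame:
    """Flatten grade profiles to one row per patient (CSV-ready)."""
    rows = []
    for pr in profiles:
        row: dict = {
            "patient_id": pr.patient_id,
            "overall_grade": pr.overall_grade,
            "grade_group": pr.grade_group,
            "postponed": pr.flags.postponed,
            "reduced": pr.flags.reduced,
            "completed": pr.flags.completed,
            "discontinued_for_haematotoxicity": pr.flags.discontinued_for_haematotoxicity,
        }
        for p, info in pr.parameters.items():
            row[f"{p}_nadir"] = info["nadir_value"]
            row[f"{p}_nadir_day"] = info["nadir_day"]
            row[f"{p}_grade"] = info["grade"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tidy-frame round trips (the CSV schema shared with the cohort generator)


def labs_to_frame(series_list: list[LabSeries]) -> pd.DataFrame:
    rows = [
        {"patient_id": s.patient_id, "sex": s.sex, "parameter": p, "day": d, "value": v, "unit": u}
        for s in series_list
        for p, recs in s.records.items()
        for d, v, u in recs
    ]
    return pd.DataFrame(rows, columns=["patient_id", "sex", "parameter", "day", "value", "unit"])


def labs_from_frame(df: pd.DataFrame) -> list[LabSeries]:
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        sex = str(grp["sex"].iloc[0]) if "sex" in grp else "female"
        records: dict[str, list[tuple[float, float, str]]] = {}
        for _, r in grp.iterrows():
            records.setdefault(str(r["parameter"]), []).append((float(r["day"]), float(r["value"]), str(r["unit"])))
        out.append(LabSeries(patient_id=str(pid), records=records, sex=sex))
    return out


def courses_to_frame(courses: list[TreatmentCourse]) -> pd.DataFrame:
    rows = [
        {"patient_id": c.patient_id, "cycle": i, "day": d, "activity_GBq": a, "discontinuation_reason": c.discontinuation_reason}
        for c in courses
        for i, d, a in c.cycles
    ]
    return pd.DataFrame(rows, columns=["patient_id", "cycle", "day", "activity_GBq", "discontinuation_reason"])


def courses_from_frame(df: pd.DataFrame) -> list[TreatmentCourse]:
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        reason = str(grp["discontinuation_reason"].iloc[0]) if "discontinuation_reason" in grp else "none"
        cycles = [(int(r["cycle"]), float(r["day"]), float(r["activity_GBq"])) for _, r in grp.iterrows()]
        out.append(TreatmentCourse(patient_id=str(pid), cycles=cycles, discontinuation_reason=reason))
    return out
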