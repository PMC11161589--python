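"""Expansion of raw per-person longitudinal records into annual person-year rows.

A person's record carries diagnosis ages, medication start ages, death and
censoring ages.  Expansion produces one row per integer age at risk, with
the current state, next-year state, and the covariate vector evaluated at
that age.  Ages are floored to integers and a year is the half-open
interval [a, a+1): a diagnosis at age 39.6 takes effect at the transition
into age 40.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .state_space import (
    CAD,
    DEATH,
    RF_CONDITIONS,
    State,
    allowed,
    state_for_rf_set,
)

__all__ = [
    "PersonRecord",
    "PersonYear",
    "COVARIATE_NAMES",
    "assign_state",
    "expand_person_years",
    "expand_cohort",
    "at_risk_set",
    "read_person_records",
    "write_person_records",
    "read_person_years",
    "write_person_years",
]

#: covariate columns, in the order used by the fitted design matrix
COVARIATE_NAMES = ("sex", "prs", "smoker", "statin_use", "antihtn_use")

MISSING = "NA"


@dataclass
class PersonRecord:
    """One subject's raw longitudinal record."""

    person_id: str
    sex: int
    prs: float
    birth_year: int
    first_obs_age: float
    censor_age: float
    smoker: int = 0
    dx_age: dict = field(default_factory=dict)  # condition -> age
    death_age: Optional[float] = None
    statin_start_age: Optional[float] = None
    antihtn_start_age: Optional[float] = None
    enroll_age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.death_age is not None:
            # death closes the record
            self.censor_age = min(self.censor_age, self.death_age)
        if self.first_obs_age > self.censor_age:
            raise ValueError(
                f"person {self.person_id}: first_obs_age {self.first_obs_age} "
                f"> censor_age {self.censor_age}"
            )
        unknown = set(self.dx_age) - set(RF_CONDITIONS) - {"CAD"}
        if unknown:
            raise ValueError(
                f"person {self.person_id}: unknown dx condition(s) {sorted(unknown)}"
            )


@dataclass(frozen=True)
class PersonYear:
    """One annual row: state at age ``age``, state at ``age + 1``, covariates."""

    person_id: str
    age: int
    from_state: State
    to_state: State
    sex: int
    prs: float
    smoker: int
    statin_use: int
    antihtn_use: int
    at_risk: bool = True
    skip: bool = False  # multi-event year: to_state jumps more than one level


def assign_state(record: PersonRecord, age: float) -> State:
    """State occupied during the year starting at ``age``.

    Death dominates, then CAD, then the accumulated risk-factor set; a
    diagnosis at fractional age ``t`` counts from the integer year
    ``floor(t)`` onward only if ``t <= age`` — i.e. effective at the next
    integer boundary.
    """
    if age < 0:
        raise ValueError("age must be nonnegative")
    if record.death_age is not None and record.death_age <= age:
        return DEATH
    cad_age = record.dx_age.get("CAD")
    if cad_age is not None and cad_age <= age:
        return CAD
    conds = [c for c in RF_CONDITIONS if record.dx_age.get(c) is not None and record.dx_age[c] <= age]
    return state_for_rf_set(conds)


def _med_use(start_age: Optional[float], age: int) -> int:
    return int(start_age is not None and start_age <= age)


def expand_person_years(
    record: PersonRecord,
    age_lo: int = 40,
    age_hi: int = 80,
) -> list[PersonYear]:
    """One row per integer age in ``[max(age_lo, first_obs), min(age_hi, censor))``.

    Rows stop at entry into an absorbing/quasi-absorbing state (CAD or
    Death): the row whose ``to_state`` is CAD or Death is the last one
    emitted.  A censoring age before ``age_lo`` yields an empty list.
    """
    if age_lo >= age_hi:
        raise ValueError(f"age_lo {age_lo} must be < age_hi {age_hi}")
    start = max(age_lo, math.ceil(record.first_obs_age))
    stop = min(age_hi, math.floor(record.censor_age))
    rows: list[PersonYear] = []
    if start >= stop:
        return rows
    from_state = assign_state(record, start)
    for age in range(start, stop):
        if from_state in (CAD, DEATH):
            break
        to_state = assign_state(record, age + 1)
        rows.append(
            PersonYear(
                person_id=record.person_id,
                age=age,
                from_state=from_state,
                to_state=to_state,
                sex=record.sex,
                prs=record.prs,
                smoker=record.smoker,
                statin_use=_med_use(record.statin_start_age, age),
                antihtn_use=_med_use(record.antihtn_start_age, age),
                at_risk=True,
                skip=not allowed(from_state, to_state),
            )
        )
        from_state = to_state
    return rows


def expand_cohort(
    records: Iterable[PersonRecord],
    age_lo: int = 40,
    age_hi: int = 80,
    exclude_baseline_cad: bool = True,
) -> pd.DataFrame:
    """Expand a whole cohort to a person-year table.

    Individuals already in CAD (or dead) at ``age_lo`` contribute nothing
    when ``exclude_baseline_cad`` is set, mirroring the baseline-CAD
    exclusion of the cohort construction.
    """
    cols: dict[str, list] = {
        "person_id": [],
        "age": [],
        "from_state": [],
        "to_state": [],
        "sex": [],
        "prs": [],
        "smoker": [],
        "statin_use": [],
        "antihtn_use": [],
        "at_risk": [],
        "skip": [],
    }
    for rec in records:
        if exclude_baseline_cad and assign_state(rec, age_lo) in (CAD, DEATH):
            continue
        for row in expand_person_years(rec, age_lo, age_hi):
            cols["person_id"].append(row.person_id)
            cols["age"].append(row.age)
            cols["from_state"].append(row.from_state.label)
            cols["to_state"].append(row.to_state.label)
            cols["sex"].append(row.sex)
            cols["prs"].append(row.prs)
            cols["smoker"].append(row.smoker)
            cols["statin_use"].append(row.statin_use)
            cols["antihtn_use"].append(row.antihtn_use)
            cols["at_risk"].append(row.at_risk)
            cols["skip"].append(row.skip)
    df = pd.DataFrame(cols)
    df["age"] = df["age"].astype(int)
    return df


def at_risk_set(
    person_years: Sequence[PersonYear],
    from_state: State,
    age: int,
) -> list[PersonYear]:
    """Rows at risk in ``from_state`` at ``age``, ordered by person_id."""
    rows = [
        r
        for r in person_years
        if r.age == age and r.from_state == from_state and r.at_risk
    ]
    rows.sort(key=lambda r: r.person_id)
    return rows


# ---------------------------------------------------------------------------
# delimited-text I/O

_RECORD_COLUMNS = [
    "person_id",
    "sex",
    "prs",
    "birth_year",
    "first_obs_age",
    "enroll_age",
    "censor_age",
    "smoker",
    "ht_dx_age",
    "hyperlip_dx_age",
    "dm_dx_age",
    "cad_dx_age",
    "death_age",
    "statin_start_age",
    "antihtn_start_age",
]

_DX_COLUMN = {"Ht": "ht_dx_age", "HyperLip": "hyperlip_dx_age", "Dm": "dm_dx_age", "CAD": "cad_dx_age"}


def _fmt(value) -> str:
    return MISSING if value is None else repr(value) if isinstance(value, float) else str(value)


def write_person_records(records: Iterable[PersonRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(_RECORD_COLUMNS) + "\n")
        for r in records:
            row = {
                "person_id": r.person_id,
                "sex": r.sex,
                "prs": r.prs,
                "birth_year": r.birth_year,
                "first_obs_age": r.first_obs_age,
                "enroll_age": r.enroll_age,
                "censor_age": r.censor_age,
                "smoker": r.smoker,
                "death_age": r.death_age,
                "statin_start_age": r.statin_start_age,
                "antihtn_start_age": r.antihtn_start_age,
            }
            for cond, col in _DX_COLUMN.items():
                row[col] = r.dx_age.get(cond)
            fh.write(",".join(_fmt(row[c]) for c in _RECORD_COLUMNS) + "\n")


def read_person_records(path) -> list[PersonRecord]:
    df = pd.read_csv(path, na_values=[MISSING], keep_default_na=False, float_precision="round_trip")
    missing = set(_RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"person-record file {path} missing columns {sorted(missing)}")

    def opt(v):
        return None if pd.isna(v) else float(v)

    records = []
    for row in df.itertuples(index=False):
        dx = {}
        for cond, col in _DX_COLUMN.items():
            v = opt(getattr(row, col))
            if v is not None:
                dx[cond] = v
        records.append(
            PersonRecord(
                person_id=str(row.person_id),
                sex=int(row.sex),
                prs=float(row.prs),
                birth_year=int(row.birth_year),
                first_obs_age=float(row.first_obs_age),
                censor_age=float(row.censor_age),
                smoker=int(row.smoker),
                dx_age=dx,
                death_age=opt(row.death_age),
                statin_start_age=opt(row.statin_start_age),
                antihtn_start_age=opt(row.antihtn_start_age),
                enroll_age=opt(row.enroll_age),
            )
        )
    return records


def write_person_years(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep=MISSING)


def read_person_years(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[MISSING], keep_default_na=False, float_precision="round_trip")
    df["age"] = df["age"].astype(int)
    for col in ("at_risk", "skip"):
        df[col] = df[col].astype(bool)
    return df
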