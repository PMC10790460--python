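"""Routine immunization schedule and derived coverage outcomes.

Encodes an EPI (Expanded Programme on Immunization) schedule as ordered
antigen-dose entries with due ages, and derives per-child analysis
outcomes from dose-receipt indicators:

* one binary column per antigen-dose (the directly observed coverage),
* ``zero``     — the child received no scheduled dose at all,
* ``full``     — fully immunized *for age* (all doses due at the child's
  age received; defined for children under 24 months),
* ``complete`` — the whole routine schedule received (children 24 months
  and older),

plus per-outcome "underage" flags marking children not yet due, the fair
source of variation in the equity analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: average calendar-month length used to convert due ages to months,
#: matching surveys that record child age in completed months
DAYS_PER_MONTH = 30.44

#: age cut separating "fully immunized for age" from "completed schedule"
FULL_AGE_CUTOFF_MONTHS = 24

#: unvaccinated children younger than this are at risk of, rather than
#: confirmed in, zero-dose status
ZERO_DOSE_AGE_MONTHS = 12


@dataclass(frozen=True)
class ScheduleEntry:
    antigen: str
    dose_number: int
    due_age_days: int
    name: str = ""

    def __post_init__(self):
        if self.dose_number < 1:
            raise ValueError("dose_number must be >= 1")
        if self.due_age_days < 0:
            raise ValueError("due_age_days must be >= 0")
        if not self.name:
            object.__setattr__(self, "name", f"{self.antigen}{self.dose_number}")

    @property
    def due_age_months(self) -> int:
        return int(np.floor(self.due_age_days / DAYS_PER_MONTH))


@dataclass(frozen=True)
class Schedule:
    entries: tuple[ScheduleEntry, ...]

    def __post_init__(self):
        keys = [(e.antigen, e.dose_number) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (antigen, dose_number) in schedule")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dose names in schedule")
        for antigen in {e.antigen for e in self.entries}:
            doses = sorted((e for e in self.entries if e.antigen == antigen),
                           key=lambda e: e.dose_number)
            ages = [e.due_age_days for e in doses]
            if ages != sorted(ages):
                raise ValueError(f"due ages must be non-decreasing within antigen {antigen!r}")

    @property
    def dose_names(self) -> list[str]:
        return [e.name for e in self.entries]

    def entry(self, name: str) -> ScheduleEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"unknown antigen-dose {name!r}")


def uganda_epi_schedule() -> Schedule:
    """Default schedule: Uganda's routine childhood schedule.

    BCG and OPV0 at birth; DPT, OPV and PCV doses 1-3 at 6/10/14 weeks;
    first measles-containing vaccine (MCV1) at 9 months. Overridable via
    run configuration; the analysis takes whatever schedule it is given.
    """
    weeks = {1: 42, 2: 70, 3: 98}
    entries = [ScheduleEntry("bcg", 1, 0, "bcg"),
               ScheduleEntry("opv", 1, 0, "opv0")]
    entries += [ScheduleEntry("opv", k + 1, d, f"opv{k}") for k, d in weeks.items()]
    entries += [ScheduleEntry("dpt", k, d) for k, d in weeks.items()]
    entries += [ScheduleEntry("pcv", k, d) for k, d in weeks.items()]
    entries.append(ScheduleEntry("mcv", 1, 274, "mcv1"))
    return Schedule(tuple(entries))


def doses_due(schedule: Schedule, age_days: int, grace_days: int = 0) -> list[str]:
    """Names of the antigen-doses due at ``age_days`` (due age <= age + grace)."""
    if age_days < 0:
        raise ValueError("age_days must be >= 0")
    return [e.name for e in schedule.entries if e.due_age_days <= age_days + grace_days]


def _due_matrix(age_months: np.ndarray, schedule: Schedule) -> pd.DataFrame:
    cols = {e.name: age_months >= e.due_age_months for e in schedule.entries}
    return pd.DataFrame(cols)


def derive_outcomes(pop: pd.DataFrame, schedule: Schedule,
                    strict_zero: bool = False) -> pd.DataFrame:
    """Derive the per-child outcome table from dose receipts and age.

    Parameters
    ----------
    pop
        Population table with ``age_months`` and one column per schedule
        dose name holding {0, 1, NaN}. Missing receipts are treated as
        not received; the recode count is reported in
        ``result.attrs["missing_dose_values"]``.
    strict_zero
        If True, ``zero`` is defined only for children aged 12 months or
        more (younger unvaccinated children get NaN). Default False:
        ``zero`` applies at any age and under-12 unvaccinated children
        additionally carry ``underage_zero = 1`` (at risk of becoming
        zero-dose), the fair covariate used downstream.
    """
    missing_cols = [c for c in schedule.dose_names if c not in pop.columns]
    if missing_cols:
        raise ValueError(f"population table lacks dose columns: {missing_cols}")

    age = pop["age_months"].to_numpy(dtype=int)
    if np.any(age < 0) or np.any(age > 59):
        raise ValueError("age_months must lie in 0-59")

    raw = pop[schedule.dose_names]
    n_missing = int(raw.isna().to_numpy().sum())
    received = raw.fillna(0.0).astype(float).to_numpy() == 1.0
    due = _due_matrix(age, schedule).to_numpy()

    out = pd.DataFrame(index=pop.index)
    for j, name in enumerate(schedule.dose_names):
        out[name] = received[:, j].astype(float)
        out[f"underage_{name}"] = (~due[:, j]).astype(float)

    none_received = ~received.any(axis=1)
    zero = none_received.astype(float)
    out["underage_zero"] = ((age < ZERO_DOSE_AGE_MONTHS) & none_received).astype(float)
    if strict_zero:
        zero = np.where(age < ZERO_DOSE_AGE_MONTHS, np.nan, zero)
    out["zero"] = zero

    # fully-immunized-for-age: every due dose received (vacuously 1 when
    # nothing is due yet); only defined under the 24-month cut
    all_due_received = (received | ~due).all(axis=1)
    under = age < FULL_AGE_CUTOFF_MONTHS
    out["full"] = np.where(under, all_due_received.astype(float), np.nan)
    out["complete"] = np.where(~under, received.all(axis=1).astype(float), np.nan)

    out.attrs["missing_dose_values"] = n_missing
    return out
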