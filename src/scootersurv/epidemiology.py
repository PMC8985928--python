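"""Patient-level aggregation, group comparisons, and utilization-corrected rates.

Confirmed injury notes are collapsed to distinct patients (care for each
patient analyzed as a unit); confirmed notes separated by more than a
configurable gap (default 30 days, mirroring the 30-day resource-abstraction
window) count as distinct accidents. Summaries stratify riders against
non-riders with chi-squared tests for categorical variables and
ANOVA/Kruskal-Wallis for continuous ones. Injury counts by index month meet
the municipal trip series to give an injury rate per million e-scooter trips
and a fatality rate per 100 million trips.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import BODY_AREAS, ClinicalNote, PatientCase, VISIT_KINDS


def notes_to_patients(
    notes: Sequence[ClinicalNote],
    gap_days: int = 30,
    structured: Mapping[str, PatientCase] | None = None,
) -> list[PatientCase]:
    """Aggregate confirmed injury notes into one case per distinct patient.

    Notes sharing a ``patient_id`` merge (so a patient found in both the
    training and testing sets is counted once). Visits union the settings of
    the patient's notes; when ``structured`` ground-truth cases are supplied
    (synthetic mode), their resource fields are merged in. Confirmed notes
    more than ``gap_days`` apart count as distinct accidents.
    """
    by_patient: dict[str, list[ClinicalNote]] = {}
    for note in notes:
        if not note.patient_id:
            raise ValueError(f"note {note.note_id} lacks a patient_id")
        if note.truth is not None and not note.is_injury:
            continue  # only confirmed injuries reach patient tallies
        by_patient.setdefault(note.patient_id, []).append(note)

    cases: list[PatientCase] = []
    for pid in sorted(by_patient):
        pnotes = sorted(by_patient[pid], key=lambda n: n.note_date)
        n_accidents = 1
        for prev, cur in zip(pnotes, pnotes[1:]):
            if (cur.note_date - prev.note_date).days > gap_days:
                n_accidents += 1
        visits = {n.setting for n in pnotes}
        base = structured.get(pid) if structured else None
        rider = (base.rider if base is not None
                 else pnotes[0].truth != "injury_nonrider")
        case = PatientCase(
            patient_id=pid,
            rider=rider,
            confirmed=True,
            body_areas=set(base.body_areas) if base else set(),
            visits=visits | (set(base.visits) if base else set()),
            imaging=set(base.imaging) if base else set(),
            procedures=set(base.procedures) if base else set(),
            physical_therapy=base.physical_therapy if base else False,
            death=base.death if base else False,
            n_distinct_accidents=max(n_accidents,
                                     base.n_distinct_accidents if base else 1),
            age=pnotes[0].age,
            sex=base.sex if base else "F",
            index_month=pd.Period(pnotes[0].note_date, freq="M"),
        )
        cases.append(case)
    return cases


# ---------------------------------------------------------------------------
# Resource summary (Table-1 style)
# ---------------------------------------------------------------------------

_AGE_BANDS = ((0, 17), (18, 25), (26, 40), (41, 64), (65, 200))
_AGE_BAND_LABELS = ("<18", "18-25", "26-40", "41-64", "65+")


def age_band(age: int) -> str:
    for (lo, hi), label in zip(_AGE_BANDS, _AGE_BAND_LABELS):
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} out of range")


#: variable name -> predicate over a PatientCase
CASE_PREDICATES = {
    "head_neck": lambda c: "head_neck" in c.body_areas,
    "chest_abdomen": lambda c: "chest_abdomen" in c.body_areas,
    "upper_ext": lambda c: "upper_ext" in c.body_areas,
    "lower_ext": lambda c: "lower_ext" in c.body_areas,
    "multiple_body_areas": lambda c: c.multiple_body_areas,
    "outpatient_visit": lambda c: "outpatient" in c.visits,
    "urgent_care_visit": lambda c: "urgent_care" in c.visits,
    "ed_visit": lambda c: "ED" in c.visits,
    "inpatient": lambda c: "inpatient" in c.visits,
    "critical_care": lambda c: "critical_care" in c.visits,
    "multiple_settings": lambda c: c.multiple_settings,
    "xray": lambda c: "xray" in c.imaging,
    "advanced_imaging": lambda c: "advanced" in c.imaging,
    "minor_procedure": lambda c: "minor" in c.procedures,
    "major_procedure": lambda c: "major" in c.procedures,
    "physical_therapy": lambda c: c.physical_therapy,
    "multiple_accidents": lambda c: c.n_distinct_accidents > 1,
    "substantial_resource_use": lambda c: c.substantial_resource_use,
    "death": lambda c: c.death,
    "male": lambda c: c.sex == "M",
}


def resource_summary(cases: Sequence[PatientCase]) -> pd.DataFrame:
    """Counts and percent-of-stratum per variable, riders vs non-riders.

    Percentages use each column's own denominator (the stratum size), as in
    patient-level injury tables.
    """
    if not cases:
        raise ValueError("cases must be nonempty")
    riders = [c for c in cases if c.rider]
    nonriders = [c for c in cases if not c.rider]
    rows = []
    for name, predicate in CASE_PREDICATES.items():
        nr = sum(predicate(c) for c in riders)
        nn = sum(predicate(c) for c in nonriders)
        rows.append(
            {
                "variable": name,
                "riders": nr,
                "riders_pct": round(100 * nr / len(riders)) if riders else 0,
                "nonriders": nn,
                "nonriders_pct": round(100 * nn / len(nonriders)) if nonriders else 0,
                "total": nr + nn,
                "total_pct": round(100 * (nr + nn) / len(cases)),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class GroupComparison:
    variable: str
    rider_counts: dict = field(default_factory=dict)
    nonrider_counts: dict = field(default_factory=dict)
    test: str = "chi_squared"
    statistic: float = float("nan")
    p_value: float = float("nan")


def compare_groups(
    cases: Sequence[PatientCase],
    variable: str,
    method: str | None = None,
) -> GroupComparison:
    """Two-sided rider vs non-rider comparison for one variable.

    Categorical variables (any :data:`CASE_PREDICATES` key, or ``age_band``
    / ``sex``) use a chi-squared test on the contingency table, without
    continuity correction; ``age`` with ``method='anova'`` or
    ``method='kruskal'`` compares the raw values.
    """
    riders = [c for c in cases if c.rider]
    nonriders = [c for c in cases if not c.rider]
    if not riders or not nonriders:
        raise ValueError("both rider strata must be nonempty")

    if variable == "age" and method in ("anova", "kruskal"):
        a = [c.age for c in riders]
        b = [c.age for c in nonriders]
        if method == "anova":
            stat, p = stats.f_oneway(a, b)
            test = "anova"
        else:
            stat, p = stats.kruskal(a, b)
            test = "kruskal_wallis"
        return GroupComparison(variable, {"mean": float(np.mean(a))},
                               {"mean": float(np.mean(b))}, test,
                               float(stat), float(p))

    if variable == "age_band":
        levels = list(_AGE_BAND_LABELS)
        value = lambda c: age_band(c.age)
    elif variable == "sex":
        levels = ["F", "M"]
        value = lambda c: c.sex
    elif variable in CASE_PREDICATES:
        levels = [False, True]
        value = CASE_PREDICATES[variable]
    else:
        raise ValueError(f"unknown variable {variable!r}")

    rc = {lvl: sum(value(c) == lvl for c in riders) for lvl in levels}
    nc = {lvl: sum(value(c) == lvl for c in nonriders) for lvl in levels}
    table = np.array(
        [[rc[lvl] for lvl in levels], [nc[lvl] for lvl in levels]], dtype=float
    )
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("contingency table has fewer than two informative levels")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return GroupComparison(variable, rc, nc, "chi_squared", float(stat), float(p))


# ---------------------------------------------------------------------------
# Monthly counts and rates
# ---------------------------------------------------------------------------

@dataclass
class MonthlyInjurySeries:
    injuries: pd.Series  # PeriodIndex('M') -> confirmed injured patients
    deaths: pd.Series    # PeriodIndex('M') -> deaths at index visit


def monthly_counts(cases: Sequence[PatientCase]) -> MonthlyInjurySeries:
    """Patients by index month (earliest encounter); deaths tracked separately."""
    if not cases:
        empty = pd.Series(dtype="int64", index=pd.PeriodIndex([], freq="M"))
        return MonthlyInjurySeries(empty, empty.copy())
    months = pd.PeriodIndex([c.index_month for c in cases], freq="M")
    full = pd.period_range(months.min(), months.max(), freq="M")
    injuries = pd.Series(0, index=full, dtype="int64")
    deaths = pd.Series(0, index=full, dtype="int64")
    for c in cases:
        m = pd.Period(c.index_month, freq="M")
        injuries[m] += 1
        if c.death:
            deaths[m] += 1
    return MonthlyInjurySeries(injuries, deaths)


@dataclass
class RateReport:
    months: pd.PeriodIndex
    mean_monthly_injuries: float
    mean_monthly_trips: float
    injuries_per_million_trips: float
    fatalities_per_100m_trips: float
    total_injuries: int
    total_trips: int
    total_deaths: int
    monthly_rates: pd.Series  # per-million rate by month; NaN where trips = 0

    def rounded(self) -> dict[str, float]:
        return {
            "injuries_per_million_trips": round(self.injuries_per_million_trips),
            "fatalities_per_100m_trips": round(self.fatalities_per_100m_trips),
            "mean_monthly_injuries": round(self.mean_monthly_injuries, 1),
            "mean_monthly_trips": round(self.mean_monthly_trips),
        }


def injury_rate(
    injuries: MonthlyInjurySeries | pd.Series,
    trips: pd.Series,
    window: tuple | None = None,
) -> RateReport:
    """Utilization-corrected injury rate over the common monthly window.

    The overall rate is the ratio of monthly means (equivalently totals over
    a shared window): 1e6 x mean injuries / mean trips per month. Fatality
    rate is 1e8 x total deaths / total trips. Months with zero trips get a
    NaN per-month rate rather than an error.
    """
    if isinstance(injuries, MonthlyInjurySeries):
        inj, deaths = injuries.injuries, injuries.deaths
    else:
        inj, deaths = injuries, pd.Series(0, index=injuries.index, dtype="int64")

    common = inj.index.intersection(trips.index)
    if window is not None:
        lo, hi = pd.Period(window[0], freq="M"), pd.Period(window[1], freq="M")
        common = common[(common >= lo) & (common <= hi)]
    if len(common) == 0:
        raise ValueError("injury and trip series share no months")
    common = common.sort_values()

    inj_w = inj.reindex(common).astype(float)
    deaths_w = deaths.reindex(common, fill_value=0).astype(float)
    trips_w = trips.reindex(common).astype(float)

    mean_inj = float(inj_w.mean())
    mean_trips = float(trips_w.mean())
    total_trips = float(trips_w.sum())
    rate = 1e6 * mean_inj / mean_trips if mean_trips > 0 else float("nan")
    fatality = (1e8 * float(deaths_w.sum()) / total_trips
                if total_trips > 0 else float("nan"))
    with np.errstate(divide="ignore", invalid="ignore"):
        monthly = 1e6 * inj_w / trips_w.replace(0, np.nan)
    return RateReport(
        months=pd.PeriodIndex(common),
        mean_monthly_injuries=mean_inj,
        mean_monthly_trips=mean_trips,
        injuries_per_million_trips=float(rate),
        fatalities_per_100m_trips=float(fatality),
        total_injuries=int(inj_w.sum()),
        total_trips=int(total_trips),
        total_deaths=int(deaths_w.sum()),
        monthly_rates=monthly,
    )
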