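"""Patient aggregation, group comparisons, and utilization-corrected rates."""
import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

import scootersurv as ss
from scootersurv.studydata import AGE_BAND_COUNTS, reference_patient_notes


def _note(note_id, patient_id, date, truth="injury_rider", setting="ED", age=30):
    return ss.ClinicalNote(note_id, patient_id, setting, date,
                           age, "fell off an e-scooter", truth=truth)


def test_distinct_patients_across_training_and_testing():
    cases = ss.notes_to_patients(reference_patient_notes())
    assert len(cases) == 1354


def test_gap_rule_separates_distinct_accidents():
    notes = [
        _note("A", "P1", dt.date(2019, 5, 1)),
        _note("B", "P1", dt.date(2019, 6, 10)),  # 40 days later
        _note("C", "P2", dt.date(2019, 5, 1)),
        _note("D", "P2", dt.date(2019, 5, 6)),  # 5 days later
    ]
    cases = {c.patient_id: c for c in ss.notes_to_patients(notes, gap_days=30)}
    assert len(cases) == 2
    assert cases["P1"].n_distinct_accidents == 2
    assert cases["P2"].n_distinct_accidents == 1


def test_resource_use_unions_across_notes():
    notes = [
        _note("A", "P1", dt.date(2019, 5, 1), setting="ED"),
        _note("B", "P1", dt.date(2019, 5, 8), setting="outpatient"),
    ]
    (case,) = ss.notes_to_patients(notes)
    assert case.visits == {"ED", "outpatient"}
    assert case.multiple_settings


def test_nonconfirmed_notes_never_become_cases():
    notes = [
        _note("A", "P1", dt.date(2019, 5, 1)),
        _note("B", "P2", dt.date(2019, 5, 1), truth="possible_injury"),
        _note("C", "P3", dt.date(2019, 5, 1), truth="confuser"),
    ]
    cases = ss.notes_to_patients(notes)
    assert [c.patient_id for c in cases] == ["P1"]


def test_missing_patient_id_rejected():
    bad = _note("A", "", dt.date(2019, 5, 1))
    with pytest.raises(ValueError):
        ss.notes_to_patients([bad])


# ---------------------------------------------------------------------------
# Resource summary
# ---------------------------------------------------------------------------

def _case(pid, rider=True, **kw):
    defaults = dict(confirmed=True, age=30, index_month=pd.Period("2019-06", "M"))
    defaults.update(kw)
    return ss.PatientCase(patient_id=pid, rider=rider, **defaults)


def test_substantial_use_percentage_from_published_totals():
    # 442 of 1,354 patients with substantial resource use -> 33%
    cases = [
        _case(f"P{i}", rider=i < 1258, physical_therapy=i < 442)
        for i in range(1354)
    ]
    table = ss.resource_summary(cases)
    row = table.loc["substantial_resource_use"]
    assert row["total"] == 442 and row["total_pct"] == 33


def test_percentages_use_stratum_denominators():
    cases = [_case(f"R{i}", rider=True, physical_therapy=True) for i in range(3)]
    cases += [_case(f"N{i}", rider=False) for i in range(7)]
    table = ss.resource_summary(cases)
    row = table.loc["physical_therapy"]
    assert row["riders_pct"] == 100 and row["nonriders_pct"] == 0
    assert row["total_pct"] == 30


def test_empty_resources_give_zero_percentages():
    cases = [_case(f"P{i}", rider=i % 2 == 0) for i in range(10)]
    table = ss.resource_summary(cases)
    for var in ("xray", "inpatient", "substantial_resource_use", "death"):
        assert table.loc[var, "total"] == 0


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def _closed_form_chi2(table):
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(((table - expected) ** 2 / expected).sum())


def test_chi_squared_matches_closed_form_on_2x2():
    cases = [_case(f"R{i}", rider=True, physical_therapy=i < 30) for i in range(100)]
    cases += [_case(f"N{i}", rider=False, physical_therapy=i < 5) for i in range(50)]
    comparison = ss.compare_groups(cases, "physical_therapy")
    expected = _closed_form_chi2([[70, 30], [45, 5]])
    assert comparison.statistic == pytest.approx(expected)
    assert comparison.test == "chi_squared"
    assert 0 <= comparison.p_value <= 1


def test_published_age_bands_differ_between_riders_and_nonriders():
    band_edges = {"<18": 15, "18-25": 20, "26-40": 30, "41-64": 50, "65+": 70}
    cases = []
    i = 0
    for label, count in zip(band_edges, AGE_BAND_COUNTS["riders"]):
        cases += [_case(f"R{i+j}", rider=True, age=band_edges[label]) for j in range(count)]
        i += count
    for label, count in zip(band_edges, AGE_BAND_COUNTS["nonriders"]):
        cases += [_case(f"N{i+j}", rider=False, age=band_edges[label]) for j in range(count)]
        i += count
    comparison = ss.compare_groups(cases, "age_band")
    assert comparison.p_value < 0.01


def test_identical_distributions_give_p_near_one():
    cases = [_case(f"R{i}", rider=True, physical_therapy=i % 2 == 0) for i in range(100)]
    cases += [_case(f"N{i}", rider=False, physical_therapy=i % 2 == 0) for i in range(100)]
    comparison = ss.compare_groups(cases, "physical_therapy")
    assert comparison.p_value > 0.99


def test_continuous_age_comparison_methods():
    rng = np.random.default_rng(0)
    cases = [_case(f"R{i}", rider=True, age=int(a)) for i, a in enumerate(rng.normal(28, 5, 80))]
    cases += [_case(f"N{i}", rider=False, age=int(a)) for i, a in enumerate(rng.normal(45, 5, 40))]
    anova = ss.compare_groups(cases, "age", method="anova")
    kruskal = ss.compare_groups(cases, "age", method="kruskal")
    assert anova.test == "anova" and anova.p_value < 0.01
    assert kruskal.test == "kruskal_wallis" and kruskal.p_value < 0.01


# ---------------------------------------------------------------------------
# Monthly counts and rates
# ---------------------------------------------------------------------------

def test_monthly_counts_conserve_cases(default_corpus):
    cfg = ss.GeneratorConfig(n_notes=2000, seed=7)
    cases = ss.generate_patient_cases(default_corpus, cfg)
    series = ss.monthly_counts(cases)
    assert int(series.injuries.sum()) == len(cases)
    assert int(series.deaths.sum()) == sum(c.death for c in cases)


def test_monthly_counts_empty_cases():
    series = ss.monthly_counts([])
    assert series.injuries.empty


def test_seasonal_generator_peaks_in_summer():
    summer, winter = [], []
    for seed in range(5):
        cfg = ss.GeneratorConfig(n_notes=3000, seasonal_amplitude=0.6, seed=seed)
        corpus = ss.generate_corpus(cfg)
        months = pd.PeriodIndex(
            [pd.Period(n.note_date, "M") for n in corpus if n.is_injury]
        )
        summer.append(sum(months.month.isin([6, 7, 8])))
        winter.append(sum(months.month.isin([12, 1, 2])))
    assert np.mean(summer) > np.mean(winter)


def _series(counts, start="2019-04", deaths=None):
    idx = pd.period_range(start, periods=len(counts), freq="M")
    inj = pd.Series(counts, index=idx, dtype="int64")
    d = pd.Series(0, index=idx, dtype="int64")
    if deaths:
        for month, k in deaths.items():
            d[pd.Period(month, "M")] = k
    return ss.MonthlyInjurySeries(inj, d)


def test_rate_arithmetic_at_published_scale():
    injuries = _series([55] * 11, deaths={"2019-08": 1})
    trips = ss.generate_trip_series(injuries.injuries.index, 477_209)
    report = ss.injury_rate(injuries, trips)
    assert report.injuries_per_million_trips == pytest.approx(1e6 * 55 / 477_209)
    assert report.rounded()["fatalities_per_100m_trips"] == 19


def test_zero_injuries_give_zero_rate():
    injuries = _series([0] * 6)
    trips = ss.generate_trip_series(injuries.injuries.index, 10_000)
    assert ss.injury_rate(injuries, trips).injuries_per_million_trips == 0.0


def test_rate_linear_in_injuries():
    injuries = _series([10, 20, 30])
    doubled = _series([20, 40, 60])
    trips = ss.generate_trip_series(injuries.injuries.index, 5_000)
    a = ss.injury_rate(injuries, trips).injuries_per_million_trips
    b = ss.injury_rate(doubled, trips).injuries_per_million_trips
    assert b == pytest.approx(2 * a)


def test_ratio_of_means_equals_ratio_of_totals():
    injuries = _series([12, 7, 31, 5])
    trips = ss.generate_trip_series(injuries.injuries.index, 8_000, 0.4, seed=2)
    report = ss.injury_rate(injuries, trips)
    assert report.injuries_per_million_trips == pytest.approx(
        1e6 * report.total_injuries / report.total_trips, abs=1e-12
    )


def test_disjoint_windows_rejected():
    injuries = _series([5, 5], start="2015-01")
    trips = ss.generate_trip_series(["2019-01", "2019-02"], 1_000)
    with pytest.raises(ValueError):
        ss.injury_rate(injuries, trips)


def test_zero_trip_month_flagged_not_fatal():
    injuries = _series([5, 5])
    idx = injuries.injuries.index
    trips = pd.Series([0, 1_000], index=idx)
    report = ss.injury_rate(injuries, trips)
    assert math.isnan(report.monthly_rates.iloc[0])
    assert not math.isnan(report.injuries_per_million_trips)
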