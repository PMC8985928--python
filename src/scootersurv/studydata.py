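"""Published reference counts used as regression fixtures.

These are the review tallies, patient counts, and exposure figures printed
by the large Los Angeles health-system surveillance study this pipeline
re-implements (36M notes screened, 2014-2020). Keeping them packaged pins
the arithmetic of the diagnostics and rate modules to the published results
forever: the numbers here are *inputs* (observed review counts and municipal
trip tallies), and every derived quantity (PPV, accuracy, LR+, adjusted
prevalence, workload, rates) is recomputed by the package at run time.
"""
from __future__ import annotations

import datetime as dt

import pandas as pd

from .diagnostics import ConfusionEstimate, StratumCounts, confusion_from_counts
from .epidemiology import MonthlyInjurySeries
from .records import ClinicalNote

# ---------------------------------------------------------------------------
# Two-phase review counts (note level)
# ---------------------------------------------------------------------------

#: ED test stratum: 47 predicted positives (43 confirmed on review); all 78
#: predicted negatives reviewed (21 injuries found), so f = 1 — no
#: extrapolation.
ED_REVIEW = StratumCounts(
    name="ED",
    true_positive=43,
    false_positive=4,
    observed_false_negative=21,
    observed_true_negative=57,
    sampling_fraction=1.0,
    n_predicted_negative=78,
)

#: Outpatient test stratum: 1,029 predicted positives (506 confirmed);
#: 12,460 predicted negatives of which a 10% sample (1,246) was reviewed,
#: finding 50 injuries.
OUTPATIENT_REVIEW = StratumCounts(
    name="outpatient",
    true_positive=506,
    false_positive=523,
    observed_false_negative=50,
    observed_true_negative=1196,
    sampling_fraction=0.10,
    n_predicted_negative=12460,
)


def reference_confusion() -> ConfusionEstimate:
    """The study's two-stratum confusion estimate, extrapolation included."""
    return confusion_from_counts([ED_REVIEW, OUTPATIENT_REVIEW])


# ---------------------------------------------------------------------------
# Patient counts
# ---------------------------------------------------------------------------

N_TRAINING_PATIENTS = 937   # distinct injured patients found while training
N_TESTING_PATIENTS = 417    # additional distinct patients found in testing
N_RIDERS = 1258
N_NONRIDERS = 96

#: Age-band x rider-status contingency counts from the patient table
#: (bands: <18, 18-25, 26-40, 41-64, 65+).
AGE_BAND_COUNTS = {
    "riders": (91, 398, 494, 251, 24),
    "nonriders": (3, 15, 24, 33, 21),
}


def reference_patient_notes() -> list[ClinicalNote]:
    """Minimal confirmed-injury notes for the published patient tallies.

    One note per distinct patient: 937 patients identified during training
    plus 417 additional patients identified during testing, with disjoint
    patient ids. Aggregating these through ``notes_to_patients`` recovers
    the published total patient count.
    """
    notes = []
    date = dt.date(2019, 6, 15)
    for i in range(N_TRAINING_PATIENTS):
        notes.append(
            ClinicalNote(f"TRN{i:05d}", f"PT{i:05d}", "ED", date, 30,
                         "fell off an e-scooter", truth="injury_rider")
        )
    for i in range(N_TESTING_PATIENTS):
        notes.append(
            ClinicalNote(f"TST{i:05d}", f"PX{i:05d}", "outpatient", date, 30,
                         "fell off an e-scooter", truth="injury_rider")
        )
    return notes


# ---------------------------------------------------------------------------
# Exposure and monthly injuries
# ---------------------------------------------------------------------------

#: Mean monthly shareable-trip tally over the window with municipal data.
MEAN_MONTHLY_TRIPS = 477_209
#: Months for which both injury and trip series exist (11 inclusive months).
TRIP_WINDOW = ("2019-04", "2020-02")
#: Traumatic deaths at the index visit during the trip window.
DEATHS_IN_WINDOW = 1

#: Monthly confirmed-injury counts over the trip window (total 604,
#: mean 54.9/month), seasonally shaped.
MONTHLY_INJURY_COUNTS = (62, 64, 66, 68, 61, 55, 48, 45, 42, 40, 53)


def reference_trip_series() -> pd.Series:
    """Flat trip series at the published monthly mean over the data window."""
    idx = pd.period_range(TRIP_WINDOW[0], TRIP_WINDOW[1], freq="M")
    return pd.Series([MEAN_MONTHLY_TRIPS] * len(idx), index=idx, name="trips")


def reference_injury_series() -> MonthlyInjurySeries:
    """Monthly injury and death counts over the trip data window."""
    idx = pd.period_range(TRIP_WINDOW[0], TRIP_WINDOW[1], freq="M")
    injuries = pd.Series(MONTHLY_INJURY_COUNTS, index=idx, dtype="int64")
    deaths = pd.Series(0, index=idx, dtype="int64")
    deaths[pd.Period("2019-08", freq="M")] = DEATHS_IN_WINDOW
    return MonthlyInjurySeries(injuries, deaths)
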