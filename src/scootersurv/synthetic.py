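"""Seeded synthetic clinical-note corpora, patient cases, and trip series.

Real injury-surveillance corpora live inside protected EHR systems, so every
stage of this pipeline is exercised on generated data that reproduces the
lexical collision structure the classifier must resolve: true e-scooter
injuries (riders and struck/tripped bystanders), "confuser" notes that match
the keyword search without being e-scooter injuries (push scooters, knee
scooters, power wheelchairs called scooters, lime-fruit allergy, Lyme
disease, the surname Byrd), ambiguous "possible" injuries, and keyword-free
negatives. Monthly seasonality is imposed on both injuries and trips.

Every function is deterministic under its seed.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    BODY_AREAS,
    ClinicalNote,
    ConfigurationError,
    PatientCase,
    SETTINGS,
)

# ---------------------------------------------------------------------------
# Default parameters
# ---------------------------------------------------------------------------

#: Patient-level probabilities used to draw body areas and 30-day resource
#: use for confirmed injuries. Values approximate the marginal frequencies
#: reported for a large published e-scooter injury cohort (N=1,354 patients).
TABLE1_DEFAULT_PROBABILITIES: dict[str, float] = {
    "head_neck": 0.43,
    "chest_abdomen": 0.10,
    "upper_ext": 0.54,
    "lower_ext": 0.47,
    "multiple_settings": 0.30,
    "outpatient_visit": 0.48,
    "urgent_care_visit": 0.06,
    "ed_visit": 0.75,
    "inpatient": 0.06,
    "critical_care_given_inpatient": 0.29,
    "xray": 0.73,
    "advanced_imaging": 0.29,
    "minor_procedure": 0.55,
    "major_procedure": 0.16,
    "physical_therapy": 0.05,
    "multiple_accidents": 0.01,
    "death": 0.0015,
    "male": 0.57,
}

_DEFAULT_CONFUSER_MIX = {
    "push_scooter": 0.30,
    "knee_scooter": 0.20,
    "power_wheelchair": 0.10,
    "lime_fruit": 0.15,
    "lyme_disease": 0.15,
    "byrd_name": 0.10,
}

_DEFAULT_SETTING_MIX = {
    "outpatient": 0.80,
    "ED": 0.14,
    "urgent_care": 0.05,
    "inpatient": 0.01,
}

# Care-setting mix conditional on note class. Injuries present mostly to the
# ED; confusers and ambiguous notes live mostly in outpatient charts, which
# recreates the strong ED-vs-outpatient prevalence contrast the triage
# arithmetic depends on.
_INJURY_SETTING_MIX = {"ED": 0.82, "outpatient": 0.05, "urgent_care": 0.08, "inpatient": 0.05}
_AMBIG_SETTING_MIX = {"ED": 0.28, "outpatient": 0.62, "urgent_care": 0.08, "inpatient": 0.02}

# Age bands (inclusive) with rider / non-rider weights.
_AGE_BANDS = ((10, 17), (18, 25), (26, 40), (41, 64), (65, 90))
_RIDER_BAND_P = (0.07, 0.32, 0.39, 0.20, 0.02)
_NONRIDER_BAND_P = (0.03, 0.16, 0.25, 0.34, 0.22)

_FOLLOWUP_P = 0.08  # fraction of injury notes that are follow-ups of a prior note


def _default_months() -> list[str]:
    return [f"2019-{m:02d}" for m in range(1, 13)]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults emulate the study conditions."""

    n_notes: int = 5000
    months: Sequence = field(default_factory=_default_months)
    injury_prevalence: float = 0.05
    rider_fraction: float = 0.93
    possible_fraction: float = 0.01
    confuser_fraction: float = 0.20
    confuser_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONFUSER_MIX)
    )
    setting_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SETTING_MIX)
    )
    age_range: tuple[int, int] = (5, 95)
    table1_probabilities: Mapping[str, float] = field(
        default_factory=lambda: dict(TABLE1_DEFAULT_PROBABILITIES)
    )
    seasonal_amplitude: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "injury_prevalence": self.injury_prevalence,
            "rider_fraction": self.rider_fraction,
            "possible_fraction": self.possible_fraction,
            "confuser_fraction": self.confuser_fraction,
            "seasonal_amplitude": self.seasonal_amplitude,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.injury_prevalence + self.possible_fraction + self.confuser_fraction > 1:
            raise ConfigurationError("class fractions exceed 1")
        for name, mix in (("confuser_mix", self.confuser_mix), ("setting_mix", self.setting_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ConfigurationError(f"{name} has a negative entry")
        if len(self.setting_mix) and not set(self.setting_mix) <= set(SETTINGS):
            raise ConfigurationError("setting_mix has unknown settings")
        if len(list(self.months)) == 0:
            raise ConfigurationError("months must be nonempty")
        lo, hi = self.age_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("invalid age_range")
        for p in self.table1_probabilities.values():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("table1_probabilities must lie in [0, 1]")

    def month_index(self) -> pd.PeriodIndex:
        idx = pd.PeriodIndex([pd.Period(m, freq="M") for m in self.months])
        if not (idx.is_monotonic_increasing and idx.is_unique):
            raise ConfigurationError("months must be strictly increasing")
        return idx


# ---------------------------------------------------------------------------
# Text templates
# ---------------------------------------------------------------------------

BRAND_NAMES = ("Bird", "Lime", "Lyft", "Bolt", "Sherpa", "Clevr", "Hopr")

_RIDER_MECHANISMS = (
    "fell off a {brand} e-scooter at speed",
    "lost control of a rental e-scooter and fell onto the pavement",
    "was riding a {brand} scooter and collided with a car",
    "crashed an electric scooter after hitting a pothole",
    "was thrown from a standing electric scooter when the front wheel locked",
    "fell off a {brand} scooter while swerving to avoid a pedestrian",
)

_NONRIDER_MECHANISMS = (
    "was struck by a passing e-scooter while crossing the street",
    "tripped over a parked {brand} scooter on the sidewalk",
    "was knocked down by an electric scooter rider on the boardwalk",
)

_ANATOMY_PHRASES = {
    "head_neck": ("head and neck", "scalp and occiput", "face and jaw"),
    "chest_abdomen": ("chest wall", "ribs and flank"),
    "upper_ext": ("right wrist", "left forearm", "shoulder and elbow"),
    "lower_ext": ("left ankle", "right knee", "hip and thigh"),
}

_INJURY_EXAM = (
    "abrasions cleaned and dressed.",
    "radiographs of the injured extremity obtained.",
    "splint applied with orthopedic follow up.",
    "laceration repaired with sutures.",
    "ct imaging ordered given mechanism.",
)

_CONFUSER_TEMPLATES = {
    "push_scooter": (
        "fell while riding a non motorized push scooter in the driveway",
        "injured on a kick scooter at the skate park, no motor involved",
    ),
    "knee_scooter": (
        "ambulating with a knee scooter following foot surgery",
        "presents for follow up, using a knee scooter for mobility after bunionectomy",
    ),
    "power_wheelchair": (
        "uses a power wheelchair, which the family refers to as a scooter, for mobility",
        "needs repair of a motorized wheelchair style mobility scooter used indoors",
    ),
    "lime_fruit": (
        "developed a blistering rash after squeezing lime juice while cooking outdoors",
        "reports an allergy to lime fruit with lip swelling after a beverage",
    ),
    "lyme_disease": (
        "evaluated for lyme disease after a deer tick bite on a weekend hike",
        "positive lyme serology, started on a course of doxycycline",
    ),
    "byrd_name": (
        "seen in consultation by dr byrd for routine chronic disease management",
        "referred to the byrd clinic for subspecialty evaluation",
    ),
    "other": (
        "uses a mobility scooter at the grocery store because of severe copd",
    ),
}

_POSSIBLE_TEMPLATES = (
    "fell off a scooter at the park, device type not documented",
    "scooter fall at school, unclear whether the scooter was motorized",
)

_NEGATIVE_COMPLAINTS = (
    "presents with sore throat and nasal congestion for three days.",
    "here for medication refill and blood pressure check.",
    "follow up of type 2 diabetes, reviewing home glucose log.",
    "twisted an ankle playing basketball yesterday evening.",
    "laceration to the finger sustained while washing dishes.",
    "chest pain, now resolved, with an unremarkable workup.",
    "annual wellness examination, no complaints today.",
    "low back pain after lifting boxes at work.",
    "headache and photophobia, improving with rest and fluids.",
    "fell from a bicycle and scraped both palms.",
    "restrained driver in a motor vehicle collision with neck strain.",
)

_FILLERS = (
    "vital signs reviewed and stable.",
    "past medical history reviewed in the chart.",
    "medications reconciled at this visit.",
    "patient counseled on strict return precautions.",
    "follow up arranged with primary care.",
    "no acute distress noted on examination.",
    "tetanus status confirmed up to date.",
    "pain controlled with oral analgesia.",
    "neurovascular examination intact distally.",
    "discharge instructions provided and understanding verbalized.",
    "denies fevers, chills, or weight loss.",
    "review of systems otherwise negative.",
)

_SETTING_PHRASE = {
    "ED": "emergency department",
    "outpatient": "clinic",
    "urgent_care": "urgent care center",
    "inpatient": "hospital ward",
}


def _filler(rng: np.random.Generator, k_lo: int = 2, k_hi: int = 4) -> str:
    k = int(rng.integers(k_lo, k_hi + 1))
    picks = rng.choice(len(_FILLERS), size=k, replace=False)
    return " ".join(_FILLERS[i] for i in picks)


def _mechanism(rng: np.random.Generator, rider: bool) -> str:
    pool = _RIDER_MECHANISMS if rider else _NONRIDER_MECHANISMS
    template = pool[int(rng.integers(len(pool)))]
    return template.format(brand=BRAND_NAMES[int(rng.integers(len(BRAND_NAMES)))])


def _injury_text(rng: np.random.Generator, age: int, setting: str, rider: bool) -> str:
    mech = _mechanism(rng, rider)
    area = BODY_AREAS[int(rng.integers(len(BODY_AREAS)))]
    phrases = _ANATOMY_PHRASES[area]
    anatomy = phrases[int(rng.integers(len(phrases)))]
    exam = _INJURY_EXAM[int(rng.integers(len(_INJURY_EXAM)))]
    return (
        f"{age} year old presents to the {_SETTING_PHRASE[setting]} after the patient "
        f"{mech}. complaining of {anatomy} pain with swelling. {exam} {_filler(rng)}"
    )


def _followup_text(rng: np.random.Generator, age: int, mech: str) -> str:
    return (
        f"{age} year old returns to the clinic for wound check after the patient "
        f"{mech}. healing appropriately. {_filler(rng)}"
    )


def _weighted_choice(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    keys = list(mix)
    p = np.asarray([mix[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _seasonal_weights(months: pd.PeriodIndex, amplitude: float) -> np.ndarray:
    # Sinusoid peaking in July, troughing in January.
    w = 1.0 + amplitude * np.cos(2 * np.pi * (np.asarray(months.month) - 7) / 12.0)
    return np.clip(w, 1e-9, None)


def _draw_date(rng: np.random.Generator, months: pd.PeriodIndex, p: np.ndarray) -> dt.date:
    m = months[int(rng.choice(len(months), p=p))]
    day = int(rng.integers(1, 29))
    return dt.date(m.year, m.month, day)


def _confuser_age(rng: np.random.Generator, kind: str, lo: int, hi: int) -> int:
    ranges = {
        "push_scooter": (5, 13),
        "knee_scooter": (30, 80),
        "power_wheelchair": (55, 90),
        "other": (55, 90),
    }
    a, b = ranges.get(kind, (18, 85))
    a, b = max(a, lo), min(b, hi)
    if b < a:
        a, b = lo, hi
    return int(rng.integers(a, b + 1))


def _injury_age(rng: np.random.Generator, rider: bool, lo: int, hi: int) -> int:
    p = _RIDER_BAND_P if rider else _NONRIDER_BAND_P
    band = _AGE_BANDS[int(rng.choice(len(_AGE_BANDS), p=np.asarray(p) / sum(p)))]
    a, b = max(band[0], lo), min(band[1], hi)
    if b < a:
        a, b = lo, hi
    return int(rng.integers(a, b + 1))


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(config: GeneratorConfig) -> list[ClinicalNote]:
    """Generate exactly ``config.n_notes`` labeled notes, deterministically.

    Class fractions follow the config in expectation. A fraction of injury
    notes are follow-up encounters for an already-injured patient (same
    ``patient_id``) so that patient-level aggregation and the distinct-
    accident gap rule have something to chew on.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 0)))
    months = config.month_index()
    seasonal_p = _seasonal_weights(months, config.seasonal_amplitude)
    seasonal_p = seasonal_p / seasonal_p.sum()
    uniform_p = np.full(len(months), 1.0 / len(months))
    lo, hi = config.age_range

    class_p = np.asarray(
        [
            config.injury_prevalence,
            config.possible_fraction,
            config.confuser_fraction,
            1.0 - config.injury_prevalence - config.possible_fraction - config.confuser_fraction,
        ]
    )
    classes = rng.choice(4, size=config.n_notes, p=class_p)

    notes: list[ClinicalNote] = []
    # (patient_id, rider, truth, age, last_date, mechanism) of injury patients
    injury_patients: list[dict] = []
    p_multi = config.table1_probabilities.get("multiple_accidents", 0.0)

    for i, cls in enumerate(classes):
        note_id = f"N{i:06d}"
        if cls == 0:  # confirmed injury (rider or non-rider)
            u = rng.random()
            if injury_patients and u < _FOLLOWUP_P:
                # Follow-up note for an existing injured patient.
                pat = injury_patients[int(rng.integers(len(injury_patients)))]
                gap = int(rng.integers(3, 22))
                date = pat["last_date"] + dt.timedelta(days=gap)
                pat["last_date"] = date
                text = _followup_text(rng, pat["age"], pat["mechanism"])
                notes.append(
                    ClinicalNote(note_id, pat["patient_id"], "outpatient", date,
                                 pat["age"], text, truth=pat["truth"])
                )
                continue
            if injury_patients and u < _FOLLOWUP_P + p_multi:
                # Second, distinct accident for an existing injured patient.
                pat = injury_patients[int(rng.integers(len(injury_patients)))]
                gap = int(rng.integers(45, 151))
                date = pat["last_date"] + dt.timedelta(days=gap)
                pat["last_date"] = date
                rider = pat["truth"] == "injury_rider"
                setting = _weighted_choice(rng, _INJURY_SETTING_MIX)
                text = _injury_text(rng, pat["age"], setting, rider)
                notes.append(
                    ClinicalNote(note_id, pat["patient_id"], setting, date,
                                 pat["age"], text, truth=pat["truth"])
                )
                continue
            rider = rng.random() < config.rider_fraction
            truth = "injury_rider" if rider else "injury_nonrider"
            age = _injury_age(rng, rider, lo, hi)
            setting = _weighted_choice(rng, _INJURY_SETTING_MIX)
            date = _draw_date(rng, months, seasonal_p)
            mech = _mechanism(rng, rider)
            area = BODY_AREAS[int(rng.integers(len(BODY_AREAS)))]
            anatomy = _ANATOMY_PHRASES[area][int(rng.integers(len(_ANATOMY_PHRASES[area])))]
            exam = _INJURY_EXAM[int(rng.integers(len(_INJURY_EXAM)))]
            text = (
                f"{age} year old presents to the {_SETTING_PHRASE[setting]} after the "
                f"patient {mech}. complaining of {anatomy} pain with swelling. "
                f"{exam} {_filler(rng)}"
            )
            pid = f"P{len(injury_patients):05d}"
            injury_patients.append(
                {"patient_id": pid, "truth": truth, "age": age,
                 "last_date": date, "mechanism": mech}
            )
            notes.append(ClinicalNote(note_id, pid, setting, date, age, text, truth=truth))
        elif cls == 1:  # possible injury: ambiguous device, young patient
            age = int(rng.integers(max(10, lo), min(16, hi) + 1))
            setting = _weighted_choice(rng, _AMBIG_SETTING_MIX)
            date = _draw_date(rng, months, seasonal_p)
            template = _POSSIBLE_TEMPLATES[int(rng.integers(len(_POSSIBLE_TEMPLATES)))]
            text = (
                f"{age} year old presents to the {_SETTING_PHRASE[setting]} after the "
                f"patient {template}. {_filler(rng)}"
            )
            notes.append(
                ClinicalNote(note_id, f"Q{i:06d}", setting, date, age, text,
                             truth="possible_injury")
            )
        elif cls == 2:  # confuser
            kind = _weighted_choice(rng, config.confuser_mix)
            age = _confuser_age(rng, kind, lo, hi)
            setting = _weighted_choice(rng, _AMBIG_SETTING_MIX)
            date = _draw_date(rng, months, uniform_p)
            pool = _CONFUSER_TEMPLATES[kind]
            body = pool[int(rng.integers(len(pool)))]
            text = (
                f"{age} year old seen in the {_SETTING_PHRASE[setting]}. the patient "
                f"{body}. {_filler(rng)}"
            )
            notes.append(
                ClinicalNote(note_id, f"C{i:06d}", setting, date, age, text,
                             truth="confuser", confuser_kind=kind)
            )
        else:  # keyword-free negative
            age = int(rng.integers(lo, hi + 1))
            setting = _weighted_choice(rng, config.setting_mix)
            date = _draw_date(rng, months, uniform_p)
            complaint = _NEGATIVE_COMPLAINTS[int(rng.integers(len(_NEGATIVE_COMPLAINTS)))]
            text = (
                f"{age} year old seen in the {_SETTING_PHRASE[setting]}. {complaint} "
                f"{_filler(rng)}"
            )
            notes.append(
                ClinicalNote(note_id, f"G{i:06d}", setting, date, age, text,
                             truth="negative")
            )
    return notes


# ---------------------------------------------------------------------------
# Patient cases
# ---------------------------------------------------------------------------

def generate_patient_cases(
    corpus: Sequence[ClinicalNote],
    config: GeneratorConfig,
    gap_days: int = 30,
) -> list[PatientCase]:
    """Draw patient-level injury structure for every confirmed injured patient.

    Body areas, imaging, and procedures are independent Bernoulli draws from
    ``config.table1_probabilities``. Care settings are drawn via an explicit
    multiple-settings probability so the fraction of patients seen in more
    than one setting matches its configured value directly. Distinct
    accidents are read off the patient's note dates (gaps > ``gap_days``).
    """
    config.validate()
    probs = config.table1_probabilities
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 1)))

    by_patient: dict[str, list[ClinicalNote]] = {}
    for note in corpus:
        if note.is_injury:
            by_patient.setdefault(note.patient_id, []).append(note)
    if not by_patient:
        raise ConfigurationError("corpus contains no confirmed injury notes")

    visit_keys = ("outpatient", "urgent_care", "ED", "inpatient")
    visit_probs = np.asarray(
        [
            probs.get("outpatient_visit", 0.0),
            probs.get("urgent_care_visit", 0.0),
            probs.get("ed_visit", 0.0),
            probs.get("inpatient", 0.0),
        ]
    )

    cases: list[PatientCase] = []
    for pid in sorted(by_patient):
        pnotes = sorted(by_patient[pid], key=lambda n: n.note_date)
        rider = pnotes[0].truth == "injury_rider"

        body = {a for a in BODY_AREAS if rng.random() < probs.get(a, 0.0)}

        visits: set[str] = set()
        total = visit_probs.sum()
        if total > 0:
            if rng.random() < probs.get("multiple_settings", 0.0):
                k = 2 if rng.random() < 0.85 else 3
                picks = rng.choice(4, size=k, replace=False, p=visit_probs / total)
                visits = {visit_keys[int(j)] for j in picks}
            else:
                visits = {visit_keys[int(rng.choice(4, p=visit_probs / total))]}
        if "inpatient" in visits and rng.random() < probs.get(
            "critical_care_given_inpatient", 0.0
        ):
            visits.add("critical_care")

        imaging = set()
        if rng.random() < probs.get("xray", 0.0):
            imaging.add("xray")
        if rng.random() < probs.get("advanced_imaging", 0.0):
            imaging.add("advanced")
        procedures = set()
        if rng.random() < probs.get("minor_procedure", 0.0):
            procedures.add("minor")
        if rng.random() < probs.get("major_procedure", 0.0):
            procedures.add("major")

        n_accidents = 1
        for prev, cur in zip(pnotes, pnotes[1:]):
            if (cur.note_date - prev.note_date).days > gap_days:
                n_accidents += 1

        cases.append(
            PatientCase(
                patient_id=pid,
                rider=rider,
                confirmed=True,
                body_areas=body,
                visits=visits,
                imaging=imaging,
                procedures=procedures,
                physical_therapy=rng.random() < probs.get("physical_therapy", 0.0),
                death=rng.random() < probs.get("death", 0.0),
                n_distinct_accidents=n_accidents,
                age=pnotes[0].age,
                sex="M" if rng.random() < probs.get("male", 0.0) else "F",
                index_month=pd.Period(pnotes[0].note_date, freq="M"),
            )
        )
    return cases


def demo_pool_config(seed: int = 0) -> GeneratorConfig:
    """A small demonstration pool with an injury-rich keyword stratum.

    Emulates the corpus that model development drew on (emergency-department
    notes, where roughly half the keyword-matching notes were real injuries),
    leaving plenty of keyword-free notes so the third training-corpus
    expansion cycle can balance negatives up to the published 1,036:1,613
    composition.
    """
    return GeneratorConfig(
        n_notes=3000,
        injury_prevalence=0.20,
        possible_fraction=0.01,
        confuser_fraction=0.10,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Trip series
# ---------------------------------------------------------------------------

def generate_trip_series(
    months: Sequence,
    mean_trips: float,
    seasonal_amplitude: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Monthly shared e-scooter trip counts with sinusoidal seasonality.

    The series is rescaled so the total equals ``round(mean_trips * n)``
    exactly (largest-remainder rounding); with ``seasonal_amplitude=0`` every
    month equals ``mean_trips``. Multiplicative jitter scales with the
    amplitude, so a purely deterministic series is the amplitude-0 limit.
    """
    if mean_trips <= 0:
        raise ConfigurationError("mean_trips must be positive")
    idx = pd.PeriodIndex([pd.Period(m, freq="M") for m in months])
    if len(idx) == 0:
        raise ConfigurationError("months must be nonempty")
    if not (idx.is_monotonic_increasing and idx.is_unique):
        raise ConfigurationError("months must be strictly increasing")
    if not 0.0 <= seasonal_amplitude <= 1.0:
        raise ConfigurationError("seasonal_amplitude must lie in [0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 2)))
    w = _seasonal_weights(idx, seasonal_amplitude)
    w = w * np.exp(rng.normal(0.0, 0.1 * seasonal_amplitude, size=len(idx)))

    target_total = int(round(mean_trips * len(idx)))
    raw = w / w.sum() * target_total
    counts = np.floor(raw).astype(np.int64)
    remainder = target_total - int(counts.sum())
    if remainder > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    return pd.Series(counts, index=idx, name="trips")
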