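"""Core record types shared across the pipeline.

The unit of NLP work is a single free-text clinical note; the unit of
epidemiology is a patient. Synthetic corpora carry a hidden ground-truth
label per note (``truth``) that real-data corpora omit.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

SETTINGS = ("ED", "outpatient", "urgent_care", "inpatient")

TRUTH_LABELS = (
    "injury_rider",
    "injury_nonrider",
    "possible_injury",
    "confuser",
    "negative",
)
INJURY_LABELS = ("injury_rider", "injury_nonrider")

CONFUSER_KINDS = (
    "push_scooter",
    "knee_scooter",
    "power_wheelchair",
    "lime_fruit",
    "lyme_disease",
    "byrd_name",
    "other",
)

BODY_AREAS = ("head_neck", "chest_abdomen", "upper_ext", "lower_ext")
VISIT_KINDS = ("outpatient", "urgent_care", "ED", "inpatient", "critical_care")


class ConfigurationError(ValueError):
    """Raised for invalid generator / pipeline configuration."""


class ParseError(ValueError):
    """Raised when an input file violates the expected schema."""


class StateError(RuntimeError):
    """Raised when an operation is applied to an unfitted/untrained model."""


@dataclass
class ClinicalNote:
    """One clinical note with metadata.

    ``truth`` and ``confuser_kind`` exist only on synthetic corpora and are
    never visible to the classifier, which reads ``text`` alone.
    """

    note_id: str
    patient_id: str
    setting: str
    note_date: dt.date
    age: int
    text: str
    truth: str | None = None
    confuser_kind: str | None = None

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ConfigurationError(f"unknown setting {self.setting!r}")
        if self.age < 0:
            raise ConfigurationError("age must be nonnegative")
        if self.truth is not None and self.truth not in TRUTH_LABELS:
            raise ConfigurationError(f"unknown truth label {self.truth!r}")
        if self.confuser_kind is not None and self.confuser_kind not in CONFUSER_KINDS:
            raise ConfigurationError(f"unknown confuser kind {self.confuser_kind!r}")

    @property
    def is_injury(self) -> bool:
        """Confirmed e-scooter injury (rider or non-rider)."""
        return self.truth in INJURY_LABELS


@dataclass
class PatientCase:
    """Patient-level injury record: rider status, anatomy, 30-day resource use."""

    patient_id: str
    rider: bool
    confirmed: bool
    body_areas: set[str] = field(default_factory=set)
    visits: set[str] = field(default_factory=set)
    imaging: set[str] = field(default_factory=set)
    procedures: set[str] = field(default_factory=set)
    physical_therapy: bool = False
    death: bool = False
    n_distinct_accidents: int = 1
    age: int = 0
    sex: str = "F"
    index_month: object = None  # pandas Period ('M') of the index encounter

    def __post_init__(self) -> None:
        if self.n_distinct_accidents < 1:
            raise ConfigurationError("n_distinct_accidents must be >= 1")
        if "critical_care" in self.visits and "inpatient" not in self.visits:
            raise ConfigurationError("critical care admission implies inpatient stay")
        if self.death and not self.confirmed:
            raise ConfigurationError("deaths are only tallied for confirmed injuries")

    @property
    def multiple_body_areas(self) -> bool:
        return len(self.body_areas) > 1

    @property
    def multiple_settings(self) -> bool:
        # critical care is a location within an inpatient stay, not a setting
        return len(self.visits - {"critical_care"}) > 1

    @property
    def substantial_resource_use(self) -> bool:
        """Multiple care settings, or any admission, major procedure, or PT."""
        return (
            self.multiple_settings
            or "inpatient" in self.visits
            or "major" in self.procedures
            or self.physical_therapy
        )
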