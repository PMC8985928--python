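"""Regular-expression keyword search and eligibility filter.

Candidate notes are selected before classification by a case-insensitive
keyword search: the word "scooter" is matched as a substring within words
(so "e-scooter", "escooter", and "scooters" all hit), while e-scooter brand
eponyms ("Bird", "Lime", "Lyft", "Bolt", "Sherpa", "Clevr", "Hopr") and
their common misspellings ("Byrd", "Lyme") are matched as whole words only —
"birdwatching" does not match "bird". Hyphens and apostrophes count as word
boundaries. Patients outside 10–90 years are excluded as unlikely e-scooter
users (boundary ages inclusive).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import ClinicalNote, ConfigurationError


@dataclass(frozen=True)
class KeywordTerm:
    term: str
    whole_word: bool = True

    def __post_init__(self) -> None:
        if not self.term or self.term != self.term.lower():
            raise ConfigurationError("keyword terms must be nonempty and lowercase")


@dataclass(frozen=True)
class KeywordSet:
    name: str
    terms: tuple[KeywordTerm, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ConfigurationError("keyword set must be nonempty")


BRAND_TERMS = ("bird", "lime", "lyft", "bolt", "sherpa", "clevr", "hopr")
MISSPELLING_TERMS = ("byrd", "lyme")

#: First-cycle search: the word "scooter" in any form, including "e-scooter".
SCOOTER_ONLY = KeywordSet("cycle1", (KeywordTerm("scooter", whole_word=False),))

#: Second-cycle search: adds brand eponyms and their misspellings, whole-word.
SCOOTER_AND_BRANDS = KeywordSet(
    "cycle2",
    (KeywordTerm("scooter", whole_word=False),)
    + tuple(KeywordTerm(t) for t in BRAND_TERMS + MISSPELLING_TERMS),
)

#: Brand-only search (cycle-2 additions), used by training-corpus expansion.
BRANDS_ONLY = KeywordSet(
    "brands", tuple(KeywordTerm(t) for t in BRAND_TERMS + MISSPELLING_TERMS)
)

# Word characters; everything else (incl. hyphen/apostrophe) is a boundary.
_WORD = "a-z0-9"


def _pattern(term: KeywordTerm) -> re.Pattern:
    escaped = re.escape(term.term)
    if term.whole_word:
        return re.compile(rf"(?<![{_WORD}]){escaped}(?![{_WORD}])")
    return re.compile(escaped)


@dataclass
class MatchResult:
    note_id: str
    matched_terms: set[str]
    eligible: bool
    exclusion_reason: str | None = None  # "age" | "no_keyword"

    def __post_init__(self) -> None:
        if self.eligible != (self.exclusion_reason is None):
            raise ConfigurationError("eligible iff no exclusion reason")


def match_keywords(text: str, keyword_set: KeywordSet) -> set[str]:
    """Return the set of keyword terms matched in ``text`` (case-insensitive)."""
    lowered = text.lower()
    return {
        t.term for t in keyword_set.terms if _pattern(t).search(lowered) is not None
    }


def classify_note(
    note: ClinicalNote,
    keyword_set: KeywordSet,
    age_min: int = 10,
    age_max: int = 90,
) -> MatchResult:
    """Eligibility for one note; age exclusion is applied before keywords."""
    matched = match_keywords(note.text, keyword_set)
    if not age_min <= note.age <= age_max:
        return MatchResult(note.note_id, matched, eligible=False, exclusion_reason="age")
    if not matched:
        return MatchResult(
            note.note_id, matched, eligible=False, exclusion_reason="no_keyword"
        )
    return MatchResult(note.note_id, matched, eligible=True)


def filter_corpus(
    corpus: Sequence[ClinicalNote],
    keyword_set: KeywordSet = SCOOTER_ONLY,
    age_min: int = 10,
    age_max: int = 90,
) -> tuple[list[ClinicalNote], dict[str, int]]:
    """Partition a corpus into eligible notes and an exclusion tally.

    Returns ``(eligible_notes, tally)`` where the tally counts
    ``eligible``, ``age``, and ``no_keyword`` and sums to ``len(corpus)``.
    """
    eligible: list[ClinicalNote] = []
    tally = {"eligible": 0, "age": 0, "no_keyword": 0}
    for note in corpus:
        result = classify_note(note, keyword_set, age_min=age_min, age_max=age_max)
        if result.eligible:
            eligible.append(note)
            tally["eligible"] += 1
        else:
            tally[result.exclusion_reason] += 1
    return eligible, tally


def keyword_free(
    corpus: Iterable[ClinicalNote], keyword_set: KeywordSet = SCOOTER_AND_BRANDS
) -> list[ClinicalNote]:
    """Notes matching no keyword at all (used to balance training negatives)."""
    return [n for n in corpus if not match_keywords(n.text, keyword_set)]
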