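"""Reading and writing the pipeline's on-disk formats.

Notes travel as JSON Lines (one note per line, UTF-8) with the hidden
ground-truth label under a ``truth`` sub-object so real-data files simply
omit it. Trip series travel as two-column CSV (``month,trips``, month as
YYYY-MM). Generator configuration loads from a YAML file with a
``generator:`` section mirroring :class:`~scootersurv.synthetic.GeneratorConfig`.
"""
from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .records import ClinicalNote, ParseError
from .synthetic import GeneratorConfig

_REQUIRED_FIELDS = ("note_id", "patient_id", "setting", "note_date", "age", "text")


def note_to_dict(note: ClinicalNote) -> dict:
    d = {
        "note_id": note.note_id,
        "patient_id": note.patient_id,
        "setting": note.setting,
        "note_date": note.note_date.isoformat(),
        "age": note.age,
        "text": note.text,
    }
    if note.truth is not None:
        truth: dict = {"label": note.truth}
        if note.confuser_kind is not None:
            truth["confuser_kind"] = note.confuser_kind
        d["truth"] = truth
    return d


def notes_to_jsonl(notes: Sequence[ClinicalNote]) -> str:
    """Serialize a corpus to a JSONL string (stable key order)."""
    return "".join(
        json.dumps(note_to_dict(n), sort_keys=True, ensure_ascii=False) + "\n"
        for n in notes
    )


def write_notes(path: str | Path, notes: Sequence[ClinicalNote]) -> None:
    Path(path).write_text(notes_to_jsonl(notes), encoding="utf-8")


def _note_from_dict(record: dict, lineno: int) -> ClinicalNote:
    for fieldname in _REQUIRED_FIELDS:
        if fieldname not in record:
            raise ParseError(f"line {lineno}: missing required field {fieldname!r}")
    truth = record.get("truth") or {}
    try:
        return ClinicalNote(
            note_id=str(record["note_id"]),
            patient_id=str(record["patient_id"]),
            setting=record["setting"],
            note_date=dt.date.fromisoformat(record["note_date"]),
            age=int(record["age"]),
            text=str(record["text"]),
            truth=truth.get("label"),
            confuser_kind=truth.get("confuser_kind"),
        )
    except (ValueError, TypeError) as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def read_notes(path: str | Path) -> list[ClinicalNote]:
    notes: list[ClinicalNote] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            note = _note_from_dict(record, lineno)
            if note.note_id in seen:
                raise ParseError(f"line {lineno}: duplicate note_id {note.note_id!r}")
            seen.add(note.note_id)
            notes.append(note)
    return notes


def write_trips(path: str | Path, trips: pd.Series) -> None:
    lines = ["month,trips"]
    for month, count in trips.items():
        lines.append(f"{pd.Period(month, freq='M')},{int(count)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trips(path: str | Path) -> pd.Series:
    months: list[pd.Period] = []
    counts: list[int] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header.lower() != "month,trips":
            raise ParseError("line 1: expected header 'month,trips'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected two fields")
            try:
                month = pd.Period(parts[0], freq="M")
                count = int(parts[1])
            except Exception as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if count < 0:
                raise ParseError(f"line {lineno}: negative trip count {count}")
            months.append(month)
            counts.append(count)
    idx = pd.PeriodIndex(months)
    if not (idx.is_monotonic_increasing and idx.is_unique):
        raise ParseError("months must be strictly increasing")
    return pd.Series(counts, index=idx, name="trips", dtype="int64")


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Load a GeneratorConfig from the ``generator:`` section of a YAML file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    section = raw.get("generator", raw)
    known = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(section) - known
    if unknown:
        raise ParseError(f"unknown generator config keys: {sorted(unknown)}")
    if "age_range" in section:
        section["age_range"] = tuple(section["age_range"])
    config = GeneratorConfig(**section)
    config.validate()
    return config
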