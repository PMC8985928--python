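"""Threshold triage and two-phase verification review.

Ensemble probabilities become review workload: a note is *predicted
positive* when its probability is at or above the triage threshold
(default 0.90, inclusive). Every predicted positive is reviewed; predicted
negatives are reviewed in a seeded uniform random sample per stratum
(emergency-department notes fully, f = 1.0; outpatient notes at f = 0.10),
which later supports inverse-probability extrapolation of the false
negatives that were never read.

Review is simulated from ground-truth labels on synthetic corpora; for real
data the same structures round-trip through a reviewer worksheet CSV.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .records import ConfigurationError

VERDICTS = ("confirmed", "possible", "non_injury")


def classify_at_threshold(probability: float, tau: float = 0.90) -> bool:
    """Predicted positive iff probability >= tau (boundary inclusive)."""
    if not 0.0 < tau < 1.0:
        raise ConfigurationError("threshold must lie strictly inside (0, 1)")
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return probability >= tau


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class Stratum:
    name: str
    predicted_positive: list[str]
    predicted_negative: list[str]
    sampling_fraction: float
    sampled_negative: list[str]
    seed: int

    def validate(self) -> None:
        if not set(self.sampled_negative) <= set(self.predicted_negative):
            raise ConfigurationError("sampled negatives must be predicted negatives")
        expected = _round_half_up(self.sampling_fraction * len(self.predicted_negative))
        if len(self.sampled_negative) != expected:
            raise ConfigurationError("sample size does not match round(f * N)")


@dataclass
class TriagePlan:
    threshold: float
    strata: dict[str, Stratum]

    def to_json(self) -> str:
        return json.dumps(
            {"threshold": self.threshold,
             "strata": {k: asdict(v) for k, v in self.strata.items()}},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "TriagePlan":
        raw = json.loads(payload)
        return cls(
            threshold=raw["threshold"],
            strata={k: Stratum(**v) for k, v in raw["strata"].items()},
        )


def build_plan(
    predictions: Mapping[str, float],
    strata_of: Mapping[str, str],
    tau: float = 0.90,
    negative_fraction: float | Mapping[str, float] = 0.10,
    seed: int = 0,
) -> TriagePlan:
    """Threshold predictions and draw the per-stratum negative review sample.

    ``negative_fraction`` may be a single fraction or a per-stratum mapping
    (e.g. ``{"ED": 1.0, "outpatient": 0.10}``). Sampling is uniform without
    replacement; sample size is round-half-up of f x N.
    """
    missing = set(predictions) - set(strata_of)
    if missing:
        raise ConfigurationError(f"{len(missing)} notes lack a stratum assignment")

    names = sorted(set(strata_of[nid] for nid in predictions))
    strata: dict[str, Stratum] = {}
    rng = np.random.default_rng(seed)
    for name in names:
        ids = sorted(nid for nid in predictions if strata_of[nid] == name)
        pos = [nid for nid in ids if classify_at_threshold(predictions[nid], tau)]
        neg = [nid for nid in ids if nid not in set(pos)]
        if isinstance(negative_fraction, Mapping):
            if name not in negative_fraction:
                raise ConfigurationError(f"no negative fraction for stratum {name!r}")
            f = float(negative_fraction[name])
        else:
            f = float(negative_fraction)
        if not 0.0 < f <= 1.0:
            if neg:
                raise ConfigurationError(
                    f"stratum {name!r}: sampling fraction must lie in (0, 1]"
                )
            f = 1.0
        n_sample = _round_half_up(f * len(neg))
        picks = rng.choice(len(neg), size=n_sample, replace=False) if n_sample else []
        sampled = [neg[int(i)] for i in sorted(picks)]
        strata[name] = Stratum(name, pos, neg, f, sampled, seed)
    return TriagePlan(threshold=tau, strata=strata)


@dataclass
class ArmCounts:
    confirmed_injury: int = 0
    possible_injury: int = 0
    non_injury: int = 0

    @property
    def total(self) -> int:
        return self.confirmed_injury + self.possible_injury + self.non_injury


@dataclass
class StratumOutcome:
    positive: ArmCounts = field(default_factory=ArmCounts)
    sampled_negative: ArmCounts = field(default_factory=ArmCounts)


@dataclass
class ReviewOutcome:
    strata: dict[str, StratumOutcome]
    possible_as_positive: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "possible_as_positive": self.possible_as_positive,
                "strata": {k: asdict(v) for k, v in self.strata.items()},
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "ReviewOutcome":
        raw = json.loads(payload)
        return cls(
            possible_as_positive=raw["possible_as_positive"],
            strata={
                k: StratumOutcome(ArmCounts(**v["positive"]),
                                  ArmCounts(**v["sampled_negative"]))
                for k, v in raw["strata"].items()
            },
        )


def _verdict_from_truth(truth: str) -> str:
    if truth in ("injury_rider", "injury_nonrider"):
        return "confirmed"
    if truth == "possible_injury":
        return "possible"
    return "non_injury"


def _tally(counts: ArmCounts, verdict: str) -> None:
    if verdict == "confirmed":
        counts.confirmed_injury += 1
    elif verdict == "possible":
        counts.possible_injury += 1
    else:
        counts.non_injury += 1


def simulate_review(
    plan: TriagePlan,
    truth_of: Mapping[str, str],
    possible_as_positive: bool = False,
) -> ReviewOutcome:
    """Replay investigator review from ground-truth labels.

    Confirmed rider/non-rider injuries review as confirmed; ambiguous
    "possible" cases count per the ``possible_as_positive`` flag downstream
    (they are tallied separately here); confusers and negatives review as
    non-injuries — uncertainty resolves conservatively to non-injury.
    """
    outcome = ReviewOutcome(strata={}, possible_as_positive=possible_as_positive)
    for name, stratum in plan.strata.items():
        so = StratumOutcome()
        for arm, counts in (
            (stratum.predicted_positive, so.positive),
            (stratum.sampled_negative, so.sampled_negative),
        ):
            for note_id in arm:
                if note_id not in truth_of:
                    raise ValueError(f"note {note_id} has no ground-truth label")
                _tally(counts, _verdict_from_truth(truth_of[note_id]))
        outcome.strata[name] = so
    return outcome


# ---------------------------------------------------------------------------
# Real-data review worksheet
# ---------------------------------------------------------------------------

def make_review_worksheet(plan: TriagePlan) -> pd.DataFrame:
    """Blank worksheet for human review: note_id, stratum, arm, verdict."""
    rows = []
    for name, stratum in plan.strata.items():
        for note_id in stratum.predicted_positive:
            rows.append((note_id, name, "positive", ""))
        for note_id in stratum.sampled_negative:
            rows.append((note_id, name, "sampled_negative", ""))
    return pd.DataFrame(rows, columns=["note_id", "stratum", "arm", "verdict"])


def ingest_review_worksheet(
    worksheet: pd.DataFrame, possible_as_positive: bool = False
) -> ReviewOutcome:
    """Tally a filled worksheet into a ReviewOutcome."""
    bad = set(worksheet["verdict"]) - set(VERDICTS)
    if bad:
        raise ConfigurationError(f"unknown verdicts in worksheet: {sorted(bad)}")
    outcome = ReviewOutcome(strata={}, possible_as_positive=possible_as_positive)
    for (name, arm), group in worksheet.groupby(["stratum", "arm"]):
        so = outcome.strata.setdefault(name, StratumOutcome())
        counts = so.positive if arm == "positive" else so.sampled_negative
        for verdict in group["verdict"]:
            _tally(counts, "confirmed" if verdict == "confirmed"
                   else "possible" if verdict == "possible" else "non_injury")
    return outcome


def write_worksheet(path: str | Path, worksheet: pd.DataFrame) -> None:
    worksheet.to_csv(path, index=False)


def read_worksheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)
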