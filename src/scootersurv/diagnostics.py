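"""Extrapolated confusion matrices and diagnostic test characteristics.

Review outcomes cover all predicted positives but only a sampled fraction f
of predicted negatives, so the negative arm is scaled by 1/f (a
Horvitz-Thompson estimate: 50 injuries found in a 10% sample of predicted
negatives imply roughly 500 missed injuries among all of them). From the
partially extrapolated matrix the usual test characteristics follow:
sensitivity, specificity, PPV, NPV, accuracy, the positive likelihood ratio
LR+ = sensitivity / (1 - specificity), and prevalence. Extrapolated counts
are kept as reals internally and rounded only for display.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.stats import norm

from .records import ConfigurationError
from .triage import ArmCounts, ReviewOutcome, TriagePlan


@dataclass
class StratumCounts:
    """Observed review counts for one stratum of the two-phase design."""

    name: str
    true_positive: int
    false_positive: int
    observed_false_negative: int
    observed_true_negative: int
    sampling_fraction: float
    n_predicted_negative: int

    def validate(self) -> None:
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ConfigurationError("sampling fraction must lie in (0, 1]")
        for v in (self.true_positive, self.false_positive,
                  self.observed_false_negative, self.observed_true_negative,
                  self.n_predicted_negative):
            if v < 0:
                raise ConfigurationError("counts must be nonnegative")


@dataclass
class StratumConfusion:
    """One stratum's confusion matrix after inverse-probability weighting."""

    name: str
    tp: float
    fp: float
    fn: float  # extrapolated = observed / f
    tn: float  # extrapolated = observed / f
    sampling_fraction: float
    observed_fn: int
    observed_tn: int
    n_predicted_negative: int

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ConfusionEstimate:
    strata: dict[str, StratumConfusion]
    combined: StratumConfusion

    def stratum(self, name: str) -> StratumConfusion:
        return self.strata[name]


def confusion_from_counts(counts: Sequence[StratumCounts]) -> ConfusionEstimate:
    """Apply 1/f weighting to the sampled-negative arm of each stratum and sum."""
    strata: dict[str, StratumConfusion] = {}
    for c in counts:
        c.validate()
        f = c.sampling_fraction
        strata[c.name] = StratumConfusion(
            name=c.name,
            tp=float(c.true_positive),
            fp=float(c.false_positive),
            fn=c.observed_false_negative / f,
            tn=c.observed_true_negative / f,
            sampling_fraction=f,
            observed_fn=c.observed_false_negative,
            observed_tn=c.observed_true_negative,
            n_predicted_negative=c.n_predicted_negative,
        )
    combined = StratumConfusion(
        name="combined",
        tp=sum(s.tp for s in strata.values()),
        fp=sum(s.fp for s in strata.values()),
        fn=sum(s.fn for s in strata.values()),
        tn=sum(s.tn for s in strata.values()),
        sampling_fraction=float("nan"),
        observed_fn=sum(s.observed_fn for s in strata.values()),
        observed_tn=sum(s.observed_tn for s in strata.values()),
        n_predicted_negative=sum(s.n_predicted_negative for s in strata.values()),
    )
    return ConfusionEstimate(strata=strata, combined=combined)


def _arm_positive(counts: ArmCounts, possible_as_positive: bool) -> int:
    return counts.confirmed_injury + (
        counts.possible_injury if possible_as_positive else 0
    )


def extrapolated_confusion(
    outcome: ReviewOutcome, plan: TriagePlan
) -> ConfusionEstimate:
    """Build the (partially extrapolated) confusion matrix from a review."""
    missing = set(plan.strata) - set(outcome.strata)
    if missing:
        raise ConfigurationError(f"review outcome missing strata: {sorted(missing)}")
    flag = outcome.possible_as_positive
    counts = []
    for name, stratum in plan.strata.items():
        so = outcome.strata[name]
        tp = _arm_positive(so.positive, flag)
        fn = _arm_positive(so.sampled_negative, flag)
        counts.append(
            StratumCounts(
                name=name,
                true_positive=tp,
                false_positive=so.positive.total - tp,
                observed_false_negative=fn,
                observed_true_negative=so.sampled_negative.total - fn,
                sampling_fraction=stratum.sampling_fraction,
                n_predicted_negative=len(stratum.predicted_negative),
            )
        )
    return confusion_from_counts(counts)


# ---------------------------------------------------------------------------
# Test characteristics
# ---------------------------------------------------------------------------

def wilson_interval(k: float, n: float, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        return (float("nan"), float("nan"))
    z = norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(center - half, 0.0), min(center + half, 1.0))


@dataclass
class TestCharacteristics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    lr_positive: float
    prevalence: float
    confidence_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    def rounded(self) -> dict[str, float]:
        """Display precision: percentages to whole percent, LR+ to 0.1."""
        out = {
            name: (round(100 * getattr(self, name))
                   if not math.isnan(getattr(self, name)) else float("nan"))
            for name in ("sensitivity", "specificity", "ppv", "npv",
                         "accuracy", "prevalence")
        }
        out["lr_positive"] = (round(self.lr_positive, 1)
                              if not math.isnan(self.lr_positive) else float("nan"))
        return out


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def test_characteristics(cm: StratumConfusion) -> TestCharacteristics:
    """Characteristics from a (possibly extrapolated) confusion matrix.

    Ratios with zero denominators are reported as NaN (not applicable),
    never raised. Wilson 95% intervals accompany each proportion, computed
    on the extrapolated counts.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    accuracy = _ratio(cm.tp + cm.tn, cm.total)
    prevalence = _ratio(cm.tp + cm.fn, cm.total)
    lr_pos = (sens / (1 - spec)
              if not math.isnan(spec) and spec < 1 and not math.isnan(sens)
              else float("nan"))
    cis = {
        "sensitivity": wilson_interval(cm.tp, cm.tp + cm.fn),
        "specificity": wilson_interval(cm.tn, cm.tn + cm.fp),
        "ppv": wilson_interval(cm.tp, cm.tp + cm.fp),
        "npv": wilson_interval(cm.tn, cm.tn + cm.fn),
        "accuracy": wilson_interval(cm.tp + cm.tn, cm.total),
    }
    return TestCharacteristics(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        accuracy=accuracy, lr_positive=lr_pos, prevalence=prevalence,
        confidence_intervals=cis,
    )


def workload_estimate(confirmed_positives: float, keyword_prevalence: float) -> int:
    """Notes a reviewer would read under keyword-only screening.

    Finding ``confirmed_positives`` injuries at a background prevalence p
    requires reviewing confirmed/p keyword-matching notes in expectation.
    """
    if keyword_prevalence <= 0:
        raise ConfigurationError("prevalence must be positive")
    return int(round(confirmed_positives / keyword_prevalence))


def adjusted_prevalence(cm: StratumConfusion, mode: str = "observed") -> float:
    """Injury prevalence among all keyword notes of a stratum.

    ``observed``: (TP + observed FN) / total keyword notes — counts only the
    injuries actually seen by reviewers. ``extrapolated``: (TP + FN/f) /
    total. The total is predicted positives plus all predicted negatives.
    """
    total = cm.tp + cm.fp + cm.n_predicted_negative
    if total <= 0:
        return 0.0
    if mode == "observed":
        return (cm.tp + cm.observed_fn) / total
    if mode == "extrapolated":
        return (cm.tp + cm.fn) / total
    raise ConfigurationError(f"unknown mode {mode!r}")


def report(estimate: ConfusionEstimate) -> dict:
    """JSON-ready report: per-stratum and combined matrices + characteristics."""
    def one(cm: StratumConfusion) -> dict:
        chars = test_characteristics(cm)
        return {
            "matrix": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "observed": {"fn": cm.observed_fn, "tn": cm.observed_tn},
            "sampling_fraction": cm.sampling_fraction,
            "characteristics": {
                "sensitivity": chars.sensitivity,
                "specificity": chars.specificity,
                "ppv": chars.ppv,
                "npv": chars.npv,
                "accuracy": chars.accuracy,
                "lr_positive": chars.lr_positive,
                "prevalence": chars.prevalence,
            },
            "display": chars.rounded(),
        }

    return {
        "strata": {name: one(cm) for name, cm in estimate.strata.items()},
        "combined": one(estimate.combined),
    }
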