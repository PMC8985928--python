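"""Threshold triage, negative sampling, and simulated review."""
import math

import numpy as np
import pytest

import scootersurv as ss
from scootersurv.records import ConfigurationError
from scootersurv.triage import (
    ingest_review_worksheet,
    make_review_worksheet,
    ReviewOutcome,
    TriagePlan,
)


def test_threshold_boundary_inclusive():
    assert ss.classify_at_threshold(0.90) is True
    assert ss.classify_at_threshold(0.8999) is False
    assert ss.classify_at_threshold(1.0) is True


def test_invalid_threshold_rejected():
    with pytest.raises(ConfigurationError):
        ss.classify_at_threshold(0.5, tau=0.0)
    with pytest.raises(ConfigurationError):
        ss.classify_at_threshold(0.5, tau=1.0)


def _toy_predictions(n=100, seed=0):
    rng = np.random.default_rng(seed)
    return {f"N{i}": float(p) for i, p in enumerate(rng.random(n))}


def test_lower_threshold_gives_superset_of_positives():
    preds = _toy_predictions()
    strata = {nid: "outpatient" for nid in preds}
    hi = ss.build_plan(preds, strata, tau=0.90, negative_fraction=1.0, seed=1)
    lo = ss.build_plan(preds, strata, tau=0.50, negative_fraction=1.0, seed=1)
    assert set(hi.strata["outpatient"].predicted_positive) <= set(
        lo.strata["outpatient"].predicted_positive
    )


def test_ten_percent_sample_of_12460_is_1246():
    preds = {f"N{i}": 0.1 for i in range(12_460)}
    strata = {nid: "outpatient" for nid in preds}
    plan = ss.build_plan(preds, strata, tau=0.90, negative_fraction=0.10, seed=2)
    stratum = plan.strata["outpatient"]
    assert len(stratum.predicted_negative) == 12_460
    assert len(stratum.sampled_negative) == 1_246
    stratum.validate()


def test_full_fraction_reviews_every_negative():
    preds = _toy_predictions(50)
    strata = {nid: "ED" for nid in preds}
    plan = ss.build_plan(preds, strata, tau=0.90, negative_fraction={"ED": 1.0}, seed=0)
    s = plan.strata["ED"]
    assert sorted(s.sampled_negative) == sorted(s.predicted_negative)


def test_sampling_deterministic_under_seed():
    preds = _toy_predictions(500)
    strata = {nid: "outpatient" for nid in preds}
    a = ss.build_plan(preds, strata, negative_fraction=0.1, seed=7)
    b = ss.build_plan(preds, strata, negative_fraction=0.1, seed=7)
    assert a.strata["outpatient"].sampled_negative == b.strata["outpatient"].sampled_negative


def test_zero_fraction_with_negatives_rejected():
    preds = _toy_predictions(50)
    strata = {nid: "outpatient" for nid in preds}
    with pytest.raises(ConfigurationError):
        ss.build_plan(preds, strata, negative_fraction=0.0, seed=0)


def test_plan_round_trips_through_json():
    preds = _toy_predictions(60)
    strata = {nid: ("ED" if int(nid[1:]) % 3 else "outpatient") for nid in preds}
    plan = ss.build_plan(preds, strata, negative_fraction={"ED": 1.0, "outpatient": 0.5}, seed=3)
    assert TriagePlan.from_json(plan.to_json()) == plan


# ---------------------------------------------------------------------------
# Simulated review
# ---------------------------------------------------------------------------

def _plan_and_truth():
    truth = {}
    preds = {}
    for i in range(10):  # injuries predicted positive
        preds[f"I{i}"] = 0.95
        truth[f"I{i}"] = "injury_rider"
    for i in range(10):  # confusers predicted positive
        preds[f"C{i}"] = 0.95
        truth[f"C{i}"] = "confuser"
    for i in range(6):  # possibles predicted positive
        preds[f"Q{i}"] = 0.95
        truth[f"Q{i}"] = "possible_injury"
    for i in range(20):  # negatives below threshold
        preds[f"N{i}"] = 0.05
        truth[f"N{i}"] = "negative" if i % 2 else "injury_nonrider"
    strata = {nid: "ED" for nid in preds}
    plan = ss.build_plan(preds, strata, negative_fraction=1.0, seed=0)
    return plan, truth


def test_review_passes_truth_labels_through():
    plan, truth = _plan_and_truth()
    outcome = ss.simulate_review(plan, truth)
    pos = outcome.strata["ED"].positive
    assert (pos.confirmed_injury, pos.possible_injury, pos.non_injury) == (10, 6, 10)
    neg = outcome.strata["ED"].sampled_negative
    assert neg.confirmed_injury == 10 and neg.non_injury == 10


def test_possible_flag_changes_only_possible_counts():
    plan, truth = _plan_and_truth()
    conservative = ss.simulate_review(plan, truth, possible_as_positive=False)
    alternate = ss.simulate_review(plan, truth, possible_as_positive=True)
    est_c = ss.extrapolated_confusion(conservative, plan)
    est_a = ss.extrapolated_confusion(alternate, plan)
    n_possible = conservative.strata["ED"].positive.possible_injury
    assert est_a.stratum("ED").tp - est_c.stratum("ED").tp == n_possible


def test_empty_plan_gives_all_zero_outcome():
    plan = ss.build_plan({}, {}, seed=0)
    outcome = ss.simulate_review(plan, {})
    assert outcome.strata == {}


def test_missing_truth_label_rejected():
    plan, truth = _plan_and_truth()
    del truth["I0"]
    with pytest.raises(ValueError, match="I0"):
        ss.simulate_review(plan, truth)


def test_review_conservation():
    plan, truth = _plan_and_truth()
    outcome = ss.simulate_review(plan, truth)
    for name, stratum in plan.strata.items():
        so = outcome.strata[name]
        assert so.positive.total == len(stratum.predicted_positive)
        assert so.sampled_negative.total == len(stratum.sampled_negative)


def test_outcome_round_trips_through_json():
    plan, truth = _plan_and_truth()
    outcome = ss.simulate_review(plan, truth)
    assert ReviewOutcome.from_json(outcome.to_json()) == outcome


def test_worksheet_round_trip_matches_simulated_review(tmp_path):
    plan, truth = _plan_and_truth()
    sheet = make_review_worksheet(plan)
    verdict = {
        "injury_rider": "confirmed", "injury_nonrider": "confirmed",
        "possible_injury": "possible", "confuser": "non_injury",
        "negative": "non_injury",
    }
    sheet["verdict"] = [verdict[truth[nid]] for nid in sheet["note_id"]]
    from scootersurv.triage import read_worksheet, write_worksheet

    write_worksheet(tmp_path / "sheet.csv", sheet)
    ingested = ingest_review_worksheet(read_worksheet(tmp_path / "sheet.csv"))
    assert ingested == ss.simulate_review(plan, truth)


def test_negative_sampling_is_unbiased():
    """Mean sampled false-negative fraction over seeded replicates ~ truth."""
    n_neg, n_fn, f = 600, 80, 0.2
    preds = {f"N{i}": 0.1 for i in range(n_neg)}
    truth = {
        f"N{i}": ("injury_rider" if i < n_fn else "negative") for i in range(n_neg)
    }
    strata = {nid: "outpatient" for nid in preds}
    n_rep = 1000
    fracs = []
    for seed in range(n_rep):
        plan = ss.build_plan(preds, strata, negative_fraction=f, seed=seed)
        sampled = plan.strata["outpatient"].sampled_negative
        fracs.append(
            sum(truth[nid] == "injury_rider" for nid in sampled) / len(sampled)
        )
    p = n_fn / n_neg
    n_sample = round(f * n_neg)
    # hypergeometric sd of the sampled fraction
    sd = math.sqrt(p * (1 - p) / n_sample * (n_neg - n_sample) / (n_neg - 1))
    se_mean = sd / math.sqrt(n_rep)
    assert abs(np.mean(fracs) - p) <= 3 * se_mean
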