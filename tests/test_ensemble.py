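"""RMDL ensemble: architecture sampling, splits, training, soft voting, AUC."""
import itertools
import warnings

import numpy as np
import pytest

import scootersurv as ss
from scootersurv.ensemble import binary_labels, expand_training_corpus
from scootersurv.prefilter import BRANDS_ONLY, match_keywords
from scootersurv.records import ConfigurationError


def test_architecture_sampling_deterministic():
    spec = ss.EnsembleSpec(seed=42)
    a = ss.build_ensemble(spec)
    b = ss.build_ensemble(ss.EnsembleSpec(seed=42))
    assert a.members == b.members
    c = ss.build_ensemble(ss.EnsembleSpec(seed=43))
    assert a.members != c.members


def test_empty_ensemble_rejected():
    with pytest.raises(ConfigurationError):
        ss.build_ensemble(ss.EnsembleSpec(n_dnn=0, n_cnn=0))


def test_collapsed_ranges_give_identical_shapes():
    spec = ss.EnsembleSpec(
        n_dnn=3, n_cnn=2,
        dnn_layer_range=(2, 2), dnn_units_range=(64, 64),
        cnn_layer_range=(1, 1), cnn_filters_range=(32, 32),
        kernel_size_range=(3, 3), seed=0,
    )
    ens = ss.build_ensemble(spec)
    dnn_shapes = {tuple(m.hidden) for m in ens.members if m.kind == "dnn"}
    cnn_shapes = {tuple(m.conv) for m in ens.members if m.kind == "cnn"}
    assert dnn_shapes == {(64, 64)} and cnn_shapes == {((32, 3),)}


def test_architectures_depend_only_on_spec(labeled_split):
    train_set, _ = labeled_split
    ens1 = ss.build_ensemble(ss.EnsembleSpec(n_dnn=1, n_cnn=1, epochs=1, seed=5))
    ens2 = ss.build_ensemble(ss.EnsembleSpec(n_dnn=1, n_cnn=1, epochs=1, seed=5))
    ss.train(ens1, train_set)
    ss.train(ens2, list(train_set) + list(train_set))  # duplicated notes
    assert ens1.members == ens2.members


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------

def test_split_sizes_and_partition(labeled_corpus):
    sub = labeled_corpus[:100]
    train_set, test_set = ss.split_labeled(sub, 0.7, seed=1)
    assert len(train_set) == 70 and len(test_set) == 30
    ids = {n.note_id for n in train_set} | {n.note_id for n in test_set}
    assert ids == {n.note_id for n in sub}
    assert not {n.note_id for n in train_set} & {n.note_id for n in test_set}


def test_split_is_label_stratified(labeled_corpus):
    y = binary_labels(labeled_corpus)
    train_set, _ = ss.split_labeled(labeled_corpus, 0.7, seed=1)
    y_train = binary_labels(train_set)
    assert abs(y_train.mean() - y.mean()) < 0.02


def test_split_deterministic(labeled_corpus):
    a, _ = ss.split_labeled(labeled_corpus, 0.7, seed=3)
    b, _ = ss.split_labeled(labeled_corpus, 0.7, seed=3)
    assert [n.note_id for n in a] == [n.note_id for n in b]


def test_split_requires_two_per_class():
    import datetime as dt

    notes = [
        ss.ClinicalNote(f"N{i}", f"P{i}", "ED", dt.date(2020, 1, 1), 30,
                        "fell off an e-scooter", truth="injury_rider")
        for i in range(5)
    ] + [
        ss.ClinicalNote("N9", "P9", "ED", dt.date(2020, 1, 1), 30,
                        "sore throat", truth="negative")
    ]
    with pytest.raises(ValueError):
        ss.split_labeled(notes, 0.7, seed=0)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _brute_force_auc(scores, labels):
    """Exhaustive pairwise concordance; ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


def test_auc_equals_pairwise_concordance_on_six_points():
    scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9]
    labels = [0, 0, 1, 1, 0, 1]
    assert ss.evaluate_auc(scores, labels) == pytest.approx(
        _brute_force_auc(scores, labels)
    )


def test_auc_perfect_separation_is_one():
    assert ss.evaluate_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0


def test_auc_all_tied_scores_is_half():
    assert ss.evaluate_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        ss.evaluate_auc([0.1, 0.9], [1, 1])


# ---------------------------------------------------------------------------
# Training and soft voting
# ---------------------------------------------------------------------------

def test_heldout_auc_on_separable_templates(trained_small, labeled_split):
    _, test_set = labeled_split
    preds = ss.predict_proba(trained_small, test_set)
    auc = ss.evaluate_auc(preds.probability, binary_labels(test_set))
    assert auc >= 0.95


def test_soft_vote_is_arithmetic_mean(trained_small, labeled_split):
    _, test_set = labeled_split
    preds = ss.predict_proba(trained_small, test_set[:50])
    np.testing.assert_allclose(
        preds.probability, preds.member_probabilities.mean(axis=1), atol=1e-9
    )
    assert (preds.probability >= preds.member_probabilities.min(axis=1) - 1e-12).all()
    assert (preds.probability <= preds.member_probabilities.max(axis=1) + 1e-12).all()
    assert ((preds.probability >= 0) & (preds.probability <= 1)).all()


def test_member_order_does_not_change_vote(trained_small, labeled_split):
    _, test_set = labeled_split
    preds = ss.predict_proba(trained_small, test_set[:20])
    reordered = preds.member_probabilities[:, ::-1]
    np.testing.assert_allclose(reordered.mean(axis=1), preds.probability, atol=1e-12)


def test_flipped_labels_invert_auc(labeled_split):
    train_set, test_set = labeled_split
    spec = ss.EnsembleSpec(n_dnn=1, n_cnn=1, epochs=4, seed=5)
    y_train = binary_labels(train_set)
    trained = ss.train(ss.build_ensemble(spec), train_set, labels=1 - y_train)
    preds = ss.predict_proba(trained, test_set)
    auc_flipped = ss.evaluate_auc(preds.probability, binary_labels(test_set))
    assert auc_flipped <= 0.05  # ~ 1 - (near-perfect original AUC)


def test_heldout_auc_nondecreasing_in_separability(labeled_split):
    """Learning sanity: less label noise, better held-out ranking."""
    train_set, test_set = labeled_split
    y_train = binary_labels(train_set)
    y_test = binary_labels(test_set)
    rng = np.random.default_rng(0)
    aucs = []
    for noise in (0.45, 0.2, 0.0):
        flip = rng.random(len(y_train)) < noise
        y_noisy = np.where(flip, 1 - y_train, y_train)
        if len(np.unique(y_noisy)) < 2:  # pragma: no cover
            y_noisy[0] = 1 - y_noisy[0]
        spec = ss.EnsembleSpec(n_dnn=1, n_cnn=1, epochs=3, seed=6)
        trained = ss.train(ss.build_ensemble(spec), train_set, labels=y_noisy)
        preds = ss.predict_proba(trained, test_set)
        aucs.append(ss.evaluate_auc(preds.probability, y_test))
    assert aucs[0] <= aucs[1] + 0.02 and aucs[1] <= aucs[2] + 0.02
    assert aucs[2] >= 0.95


def test_single_class_training_rejected(labeled_corpus):
    injuries = [n for n in labeled_corpus if n.is_injury][:10]
    spec = ss.EnsembleSpec(n_dnn=1, n_cnn=0, epochs=1, seed=0)
    with pytest.raises(ValueError):
        ss.train(ss.build_ensemble(spec), injuries)


def test_save_load_round_trip(tmp_path, trained_small, labeled_split):
    _, test_set = labeled_split
    before = ss.predict_proba(trained_small, test_set[:30])
    ss.save_ensemble(trained_small, tmp_path / "model")
    loaded = ss.load_ensemble(tmp_path / "model")
    after = ss.predict_proba(loaded, test_set[:30])
    np.testing.assert_allclose(after.probability, before.probability, atol=1e-6)


# ---------------------------------------------------------------------------
# Iterative corpus expansion
# ---------------------------------------------------------------------------

def test_stage_one_adds_scooter_notes(demo_pool):
    corpus = expand_training_corpus(1, [], demo_pool, seed=0)
    from scootersurv.prefilter import SCOOTER_ONLY

    assert corpus
    for note in corpus:
        assert match_keywords(note.text, SCOOTER_ONLY)


def test_stage_two_additions_all_contain_brand_terms(demo_pool):
    base = expand_training_corpus(1, [], demo_pool, seed=0)
    grown = expand_training_corpus(2, base, demo_pool, seed=0)
    added = grown[len(base):]
    for note in added:
        assert match_keywords(note.text, BRANDS_ONLY), note.text


def test_stage_three_with_no_keyword_free_pool_warns(demo_pool):
    base = expand_training_corpus(1, [], demo_pool, seed=0)
    keyword_pool = [n for n in demo_pool if n.truth != "negative"]
    with pytest.warns(UserWarning, match="exhausted"):
        grown = expand_training_corpus(3, base, keyword_pool, seed=0)
    assert {n.note_id for n in grown} >= {n.note_id for n in base}


def test_three_stages_hit_published_class_balance(labeled_corpus):
    y = binary_labels(labeled_corpus)
    target = 1036 / (1036 + 1613)
    assert abs(y.mean() - target) < 0.05
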