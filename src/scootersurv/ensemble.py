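"""Random multimodel deep learning (RMDL) ensemble.

Several feedforward networks over TF-IDF vectors and several convolutional
networks over word-embedding sequences, each with depth/width/kernel
hyperparameters drawn uniformly at random from configured ranges, trained
independently and combined by *soft voting*: the ensemble probability of
e-scooter injury is the unweighted arithmetic mean of the member
probabilities. Architecture sampling and every member's weight
initialization derive from a single spec seed through numpy SeedSequence
spawning, so a spec is fully reproducible.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from . import prefilter
from .nets import ConvNet, DenseNet
from .records import ClinicalNote, ConfigurationError, StateError
from .text import (
    EmbeddingModel,
    TfidfModel,
    encode_indices,
    fit_embeddings,
    fit_tfidf,
    preprocess,
    transform_tfidf,
)

#: Negative:positive balance targeted by the third corpus-expansion cycle,
#: matching the composition of the study's final labeled corpus
#: (1,036 confirmed injuries : 1,613 confirmed negatives).
TARGET_NEGATIVE_RATIO = 1613 / 1036


@dataclass
class EnsembleSpec:
    """Hyperparameter ranges for randomly configured members."""

    n_dnn: int = 3
    n_cnn: int = 3
    dnn_layer_range: tuple[int, int] = (1, 3)
    dnn_units_range: tuple[int, int] = (32, 128)
    cnn_layer_range: tuple[int, int] = (1, 2)
    cnn_filters_range: tuple[int, int] = (16, 48)
    kernel_size_range: tuple[int, int] = (3, 5)
    dropout: float = 0.2
    epochs: int = 8
    batch_size: int = 64
    seed: int = 0
    # feature configuration
    tfidf_min_df: int = 2
    tfidf_max_features: int | None = 2000
    embedding_dimension: int = 50
    max_sequence_length: int = 60

    def validate(self) -> None:
        if self.n_dnn + self.n_cnn < 1:
            raise ConfigurationError("ensemble needs at least one member")
        if self.n_dnn < 0 or self.n_cnn < 0:
            raise ConfigurationError("member counts must be nonnegative")
        for name in ("dnn_layer_range", "dnn_units_range", "cnn_layer_range",
                     "cnn_filters_range", "kernel_size_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{name} must be a nonempty integer range")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be positive")


@dataclass
class MemberSpec:
    kind: str  # "dnn" | "cnn"
    hidden: list[int] = field(default_factory=list)       # dnn widths
    conv: list[tuple[int, int]] = field(default_factory=list)  # (filters, kernel)
    seed: int = 0


@dataclass
class Ensemble:
    """Untrained ensemble: the spec plus its sampled member architectures."""

    spec: EnsembleSpec
    members: list[MemberSpec]


def build_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Sample member architectures uniformly from the spec ranges, seeded."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    arch_rng = np.random.default_rng(root.spawn(1)[0])
    member_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(spec.n_dnn + spec.n_cnn + 1)[1:]]

    members: list[MemberSpec] = []
    for i in range(spec.n_dnn):
        depth = int(arch_rng.integers(spec.dnn_layer_range[0], spec.dnn_layer_range[1] + 1))
        hidden = [int(arch_rng.integers(spec.dnn_units_range[0], spec.dnn_units_range[1] + 1))
                  for _ in range(depth)]
        members.append(MemberSpec("dnn", hidden=hidden, seed=member_seeds[i]))
    for i in range(spec.n_cnn):
        depth = int(arch_rng.integers(spec.cnn_layer_range[0], spec.cnn_layer_range[1] + 1))
        conv = [
            (
                int(arch_rng.integers(spec.cnn_filters_range[0], spec.cnn_filters_range[1] + 1)),
                int(arch_rng.integers(spec.kernel_size_range[0], spec.kernel_size_range[1] + 1)),
            )
            for _ in range(depth)
        ]
        members.append(MemberSpec("cnn", conv=conv, seed=member_seeds[spec.n_dnn + i]))
    return Ensemble(spec=spec, members=members)


# ---------------------------------------------------------------------------
# Labels and splits
# ---------------------------------------------------------------------------

def binary_labels(notes: Sequence[ClinicalNote]) -> np.ndarray:
    """1 for confirmed e-scooter injury, 0 otherwise (possible counts as 0)."""
    labels = []
    for n in notes:
        if n.truth is None:
            raise ValueError(f"note {n.note_id} has no ground-truth label")
        labels.append(1 if n.is_injury else 0)
    return np.asarray(labels, dtype=np.int64)


def split_labeled(
    notes: Sequence[ClinicalNote],
    train_fraction: float = 0.70,
    seed: int = 0,
) -> tuple[list[ClinicalNote], list[ClinicalNote]]:
    """Label-stratified random split into train/test subsets."""
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must lie in (0, 1)")
    y = binary_labels(notes)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 notes in each class to split")
    train, test = train_test_split(
        list(notes), train_size=train_fraction, stratify=y, random_state=seed
    )
    return list(train), list(test)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedEnsemble:
    ensemble: Ensemble
    tfidf: TfidfModel
    embeddings: EmbeddingModel
    nets: list[object]
    metrics: dict = field(default_factory=dict)

    @property
    def members(self) -> list[MemberSpec]:
        return self.ensemble.members


@dataclass
class PredictionSet:
    """Per-note ensemble output; probability is the mean over members."""

    note_ids: list[str]
    member_probabilities: np.ndarray  # (n_notes, n_members)
    probability: np.ndarray           # (n_notes,)

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.note_ids, map(float, self.probability)))


def _features(
    tfidf: TfidfModel, embeddings: EmbeddingModel, documents: Sequence[list[str]]
) -> tuple[np.ndarray, np.ndarray]:
    dense = transform_tfidf(tfidf, documents).toarray()
    idx = np.stack([encode_indices(embeddings, doc) for doc in documents])
    return dense, idx


def train(
    ensemble: Ensemble,
    train_notes: Sequence[ClinicalNote],
    labels: Sequence[int] | None = None,
) -> TrainedEnsemble:
    """Fit features and every member on the training notes.

    Labels default to ground truth (confirmed injury vs not); pass ``labels``
    explicitly for reviewer-supplied labels in real-data mode.
    """
    spec = ensemble.spec
    y = np.asarray(labels, dtype=np.int64) if labels is not None else binary_labels(train_notes)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    documents = [preprocess(n.text) for n in train_notes]
    tfidf = fit_tfidf(documents, min_df=spec.tfidf_min_df,
                      max_features=spec.tfidf_max_features)
    embeddings = fit_embeddings(
        documents,
        dimension=spec.embedding_dimension,
        max_sequence_length=spec.max_sequence_length,
        seed=spec.seed,
    )
    X_tfidf, X_idx = _features(tfidf, embeddings, documents)

    nets: list[object] = []
    for member in ensemble.members:
        if member.kind == "dnn":
            net = DenseNet(
                input_dim=X_tfidf.shape[1], hidden=member.hidden,
                dropout=spec.dropout, epochs=spec.epochs,
                batch_size=spec.batch_size, seed=member.seed,
            ).fit(X_tfidf, y)
        else:
            net = ConvNet(
                embedding_matrix=embeddings.matrix, conv_layers=member.conv,
                dropout=spec.dropout, epochs=spec.epochs,
                batch_size=spec.batch_size, seed=member.seed,
            ).fit(X_idx, y)
        nets.append(net)

    trained = TrainedEnsemble(ensemble=ensemble, tfidf=tfidf,
                              embeddings=embeddings, nets=nets)
    preds = predict_proba(trained, train_notes)
    member_auc = [
        float(roc_auc_score(y, preds.member_probabilities[:, j]))
        for j in range(preds.member_probabilities.shape[1])
    ]
    trained.metrics = {
        "train_auc": float(roc_auc_score(y, preds.probability)),
        "member_train_auc": member_auc,
        "n_train": len(train_notes),
    }
    return trained


def predict_proba(
    trained: TrainedEnsemble, notes: Sequence[ClinicalNote]
) -> PredictionSet:
    """Soft-vote member probabilities: the unweighted arithmetic mean."""
    if not trained.nets:
        raise StateError("ensemble has no trained members")
    documents = [preprocess(n.text) for n in notes]
    X_tfidf, X_idx = _features(trained.tfidf, trained.embeddings, documents)
    cols = []
    for member, net in zip(trained.ensemble.members, trained.nets):
        X = X_tfidf if member.kind == "dnn" else X_idx
        cols.append(net.predict_proba(X))
    member_probs = np.column_stack(cols)
    return PredictionSet(
        note_ids=[n.note_id for n in notes],
        member_probabilities=member_probs,
        probability=member_probs.mean(axis=1),
    )


def evaluate_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney concordance; ties count half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Iterative training-corpus expansion
# ---------------------------------------------------------------------------

def expand_training_corpus(
    stage: int,
    base: Sequence[ClinicalNote],
    pool: Sequence[ClinicalNote],
    seed: int = 0,
    negative_ratio: float = TARGET_NEGATIVE_RATIO,
) -> list[ClinicalNote]:
    """One cycle of labeled-corpus growth against a note pool.

    Stage 1 adds every pool note matching the word "scooter"; stage 2 adds
    notes matching brand eponyms or their misspellings; stage 3 balances the
    corpus with randomly sampled keyword-free notes (labels always come from
    ground truth, standing in for manual review). Returns a new corpus; the
    base is never mutated. An exhausted pool triggers a warning, not an error.
    """
    if stage not in (1, 2, 3):
        raise ConfigurationError("stage must be 1, 2, or 3")
    existing = {n.note_id for n in base}
    corpus = list(base)
    candidates = [n for n in pool if n.note_id not in existing]

    if stage == 1:
        added = [n for n in candidates
                 if prefilter.match_keywords(n.text, prefilter.SCOOTER_ONLY)]
    elif stage == 2:
        added = [n for n in candidates
                 if prefilter.match_keywords(n.text, prefilter.BRANDS_ONLY)]
    else:
        free = prefilter.keyword_free(candidates)
        y = binary_labels(corpus) if corpus else np.zeros(0, dtype=np.int64)
        n_pos = int(y.sum())
        n_neg = len(y) - n_pos
        want = max(int(round(negative_ratio * n_pos)) - n_neg, 0)
        if want > len(free):
            warnings.warn(
                f"keyword-free pool exhausted: wanted {want} negatives, "
                f"found {len(free)}",
                stacklevel=2,
            )
            want = len(free)
        rng = np.random.default_rng(seed)
        picks = rng.choice(len(free), size=want, replace=False) if want else []
        added = [free[int(i)] for i in sorted(picks)]

    if stage in (1, 2) and not added:
        warnings.warn(f"stage {stage}: pool contributed no new notes", stacklevel=2)
    return corpus + added


def build_labeled_corpus(
    pool: Sequence[ClinicalNote], seed: int = 0
) -> list[ClinicalNote]:
    """Run all three expansion cycles against a pool, starting from nothing."""
    corpus: list[ClinicalNote] = []
    for stage in (1, 2, 3):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corpus = expand_training_corpus(stage, corpus, pool, seed=seed)
    return corpus


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_ensemble(trained: TrainedEnsemble, directory: str | Path) -> None:
    """Save a directory bundle: JSON manifest + npz weight files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "spec": asdict(trained.ensemble.spec),
        "members": [asdict(m) for m in trained.ensemble.members],
        "metrics": trained.metrics,
        "tfidf": {
            "vocabulary": {k: int(v) for k, v in trained.tfidf.vocabulary.items()},
            "idf": trained.tfidf.idf,
            "min_df": trained.tfidf.min_df,
            "max_features": trained.tfidf.max_features,
        },
        "embedding_vocabulary": trained.embeddings.vocabulary,
        "max_sequence_length": trained.embeddings.max_sequence_length,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest), encoding="utf-8")
    np.savez(directory / "embeddings.npz", matrix=trained.embeddings.matrix)
    for i, net in enumerate(trained.nets):
        np.savez(directory / f"member_{i}.npz",
                 *[np.asarray(p) for p in net.params])


def load_ensemble(directory: str | Path) -> TrainedEnsemble:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
    spec = EnsembleSpec(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in manifest["spec"].items()
    })
    members = [
        MemberSpec(kind=m["kind"], hidden=list(m["hidden"]),
                   conv=[tuple(c) for c in m["conv"]], seed=m["seed"])
        for m in manifest["members"]
    ]
    matrix = np.load(directory / "embeddings.npz")["matrix"]
    embeddings = EmbeddingModel(
        dimension=matrix.shape[1],
        vocabulary={k: int(v) for k, v in manifest["embedding_vocabulary"].items()},
        matrix=matrix,
        max_sequence_length=int(manifest["max_sequence_length"]),
    )
    # rebuild the sklearn vectorizer from stored vocabulary and idf
    from sklearn.feature_extraction.text import TfidfVectorizer
    from .text import _identity

    tf = manifest["tfidf"]
    vocab = {k: int(v) for k, v in tf["vocabulary"].items()}
    vectorizer = TfidfVectorizer(
        analyzer=_identity, lowercase=False, smooth_idf=True, norm="l2",
        vocabulary=vocab,
    )
    idf = np.empty(len(vocab))
    for term, i in vocab.items():
        idf[i] = tf["idf"][term]
    vectorizer.idf_ = idf
    tfidf = TfidfModel(min_df=tf["min_df"], max_features=tf["max_features"])
    tfidf._vectorizer = vectorizer

    nets: list[object] = []
    for i, member in enumerate(members):
        data = np.load(directory / f"member_{i}.npz")
        params = [data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))]
        if member.kind == "dnn":
            net = DenseNet(input_dim=params[0].shape[0], hidden=member.hidden,
                           dropout=spec.dropout, seed=member.seed)
        else:
            net = ConvNet(embedding_matrix=matrix, conv_layers=member.conv,
                          dropout=spec.dropout, seed=member.seed)
        net.params = params
        nets.append(net)
    return TrainedEnsemble(
        ensemble=Ensemble(spec=spec, members=members),
        tfidf=tfidf, embeddings=embeddings, nets=nets,
        metrics=manifest.get("metrics", {}),
    )
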