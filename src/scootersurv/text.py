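"""Preprocessing and the two feature representations feeding the ensemble.

Notes are lowercased, tokenized on punctuation, stop-word filtered, and
Porter-stemmed. Two representations are then built:

* **TF-IDF vectors** (smoothed idf, L2-normalized) feeding the feedforward
  ensemble members — computed with scikit-learn over the pre-tokenized
  sequences;
* **word-embedding sequences** feeding the convolutional members. Embeddings
  are trained locally from corpus co-occurrence statistics (positive
  pointwise mutual information factorized by truncated SVD), so no download
  is required; a loader accepts standard whitespace-delimited word-vector
  text files for parity with pretrained GloVe vectors.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.exceptions import NotFittedError
from sklearn.feature_extraction.text import TfidfVectorizer

from .records import ParseError, StateError
from .stem import STOPWORDS, porter_stem

_TOKEN_RE = re.compile(r"[a-z]+")


def _stem_fixpoint(token: str) -> str:
    # iterate the suffix stripper to a fixed point so that preprocessing is
    # idempotent (plain Porter is not: glucose -> glucos -> gluco)
    while True:
        stemmed = porter_stem(token)
        if stemmed == token:
            return token
        token = stemmed


def preprocess(text: str) -> list[str]:
    """Lowercase, tokenize, remove stop words, stem. Deterministic, idempotent.

    Tokenization keeps alphabetic runs only; the Porter stemmer is applied to
    a fixed point, and stop words are filtered both before and after stemming
    so re-preprocessing its own output is a no-op.
    """
    tokens = _TOKEN_RE.findall(text.lower())
    stems = (
        _stem_fixpoint(t) for t in tokens if t not in STOPWORDS and len(t) > 1
    )
    return [s for s in stems if s not in STOPWORDS and len(s) > 1]


# ---------------------------------------------------------------------------
# TF-IDF
# ---------------------------------------------------------------------------

def _identity(tokens: list[str]) -> list[str]:
    return tokens


@dataclass
class TfidfModel:
    """Fitted TF-IDF weighting: weight(t, d) = tf(t, d) * idf(t), L2-normalized."""

    min_df: int = 1
    max_features: int | None = None
    _vectorizer: TfidfVectorizer | None = field(default=None, repr=False)

    @property
    def vocabulary(self) -> dict[str, int]:
        self._check_fitted()
        return dict(self._vectorizer.vocabulary_)

    @property
    def idf(self) -> dict[str, float]:
        self._check_fitted()
        vocab = self._vectorizer.vocabulary_
        idf = self._vectorizer.idf_
        return {term: float(idf[i]) for term, i in vocab.items()}

    def _check_fitted(self) -> None:
        if self._vectorizer is None:
            raise StateError("TF-IDF model has not been fitted")


def fit_tfidf(
    documents: Sequence[list[str]],
    min_df: int = 1,
    max_features: int | None = None,
) -> TfidfModel:
    """Fit TF-IDF on pre-tokenized documents (smoothed idf, L2 norm)."""
    if len(documents) == 0:
        raise ValueError("need at least one document")
    vectorizer = TfidfVectorizer(
        analyzer=_identity,
        lowercase=False,
        min_df=min_df,
        max_features=max_features,
        smooth_idf=True,
        sublinear_tf=False,
        norm="l2",
    )
    vectorizer.fit(list(documents))
    model = TfidfModel(min_df=min_df, max_features=max_features)
    model._vectorizer = vectorizer
    return model


def transform_tfidf(model: TfidfModel, documents: Sequence[list[str]]) -> sp.csr_matrix:
    """Weight documents under a fitted model; out-of-vocabulary terms ignored."""
    model._check_fitted()
    try:
        return model._vectorizer.transform(list(documents))
    except NotFittedError as exc:  # pragma: no cover - guarded above
        raise StateError("TF-IDF model has not been fitted") from exc


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingModel:
    """Token vectors plus the padding policy for fixed-length encoding.

    ``matrix`` has shape (V + 1, dimension); row 0 is the shared
    padding/unknown vector (all zeros), token rows start at index 1.
    """

    dimension: int
    vocabulary: dict[str, int]  # token -> row index in ``matrix`` (>= 1)
    matrix: np.ndarray
    max_sequence_length: int = 60

    def vector(self, token: str) -> np.ndarray:
        return self.matrix[self.vocabulary.get(token, 0)]


def fit_embeddings(
    documents: Sequence[list[str]],
    dimension: int = 50,
    max_sequence_length: int = 60,
    window: int = 5,
    min_count: int = 2,
    seed: int = 0,
) -> EmbeddingModel:
    """Train embeddings from corpus co-occurrence (PPMI + truncated SVD).

    Symmetric context window with 1/distance weighting; positive PMI matrix
    factorized with sparse SVD; vectors are U * sqrt(S) with a deterministic
    sign convention, so identical seeds give identical vectors.
    """
    if len(documents) == 0:
        raise ValueError("corpus must be nonempty")
    if dimension < 2:
        raise ValueError("dimension must be >= 2")

    counts: dict[str, int] = {}
    for doc in documents:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    vocab_tokens = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab_tokens:
        vocab_tokens = sorted(counts)
    index = {t: i for i, t in enumerate(vocab_tokens)}
    v = len(index)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for doc in documents:
        ids = [index[t] for t in doc if t in index]
        for i, a in enumerate(ids):
            for off in range(1, window + 1):
                j = i + off
                if j >= len(ids):
                    break
                w = 1.0 / off
                rows.extend((a, ids[j]))
                cols.extend((ids[j], a))
                vals.extend((w, w))
    cooc = sp.coo_matrix((vals, (rows, cols)), shape=(v, v)).tocsr()

    total = cooc.sum()
    row_sums = np.asarray(cooc.sum(axis=1)).ravel()
    coo = cooc.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log(coo.data * total / (row_sums[coo.row] * row_sums[coo.col]))
    keep = pmi > 0
    ppmi = sp.coo_matrix(
        (pmi[keep], (coo.row[keep], coo.col[keep])), shape=(v, v)
    ).tocsr()

    k = min(dimension, max(v - 1, 1))
    rng = np.random.default_rng(seed)
    if v > 1 and ppmi.nnz > 0:
        u, s, _ = svds(ppmi, k=k, v0=rng.standard_normal(v))
        order = np.argsort(-s)
        u, s = u[:, order], s[order]
        # fix SVD sign ambiguity: largest-magnitude loading positive
        for j in range(u.shape[1]):
            if u[np.argmax(np.abs(u[:, j])), j] < 0:
                u[:, j] = -u[:, j]
        vectors = u * np.sqrt(s)
    else:
        vectors = np.zeros((v, k))
    if k < dimension:
        vectors = np.pad(vectors, ((0, 0), (0, dimension - k)))

    matrix = np.zeros((v + 1, dimension), dtype=np.float32)
    matrix[1:] = vectors.astype(np.float32)
    vocabulary = {t: i + 1 for t, i in index.items()}
    return EmbeddingModel(dimension, vocabulary, matrix, max_sequence_length)


def encode_indices(model: EmbeddingModel, tokens: Sequence[str]) -> np.ndarray:
    """Token row-indices padded/truncated to ``max_sequence_length`` (0 = pad/unknown)."""
    length = model.max_sequence_length
    out = np.zeros(length, dtype=np.int32)
    for i, tok in enumerate(tokens[:length]):
        out[i] = model.vocabulary.get(tok, 0)
    return out


def encode(model: EmbeddingModel, tokens: Sequence[str]) -> np.ndarray:
    """Fixed-length sequence of vectors, shape (max_sequence_length, dimension)."""
    return model.matrix[encode_indices(model, tokens)]


def cosine_similarity(model: EmbeddingModel, a: str, b: str) -> float:
    va, vb = model.vector(a), model.vector(b)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(va @ vb / (na * nb))


def load_word_vectors(
    path: str | Path, max_sequence_length: int = 60
) -> EmbeddingModel:
    """Load the whitespace-delimited ``token v1 ... vd`` word-vector format."""
    vocabulary: dict[str, int] = {}
    vectors: list[np.ndarray] = []
    dimension: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            token, values = parts[0], parts[1:]
            if dimension is None:
                dimension = len(values)
                if dimension < 1:
                    raise ParseError(f"line {lineno}: no vector components")
            if len(values) != dimension:
                raise ParseError(
                    f"line {lineno}: expected {dimension} components, got {len(values)}"
                )
            try:
                vec = np.asarray([float(x) for x in values], dtype=np.float32)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            vocabulary[token] = len(vectors) + 1
            vectors.append(vec)
    if dimension is None:
        raise ParseError("empty word-vector file")
    matrix = np.zeros((len(vectors) + 1, dimension), dtype=np.float32)
    matrix[1:] = np.stack(vectors)
    return EmbeddingModel(dimension, vocabulary, matrix, max_sequence_length)
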