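"""N-gram featurization, cosine similarity, and context features.

Text becomes a documents x n-grams count (or tf-idf) matrix over a
first-occurrence-ordered unigram+bigram vocabulary. Context features —
the non-text catalogue columns: review-percentage triplet scaled to [0, 1]
and one-hot manufacturer indicators — are appended to make the feature
space "context aware". Cosine similarity between document vectors is
available as a separate square matrix; a zero-norm row is orthogonal to
everything but keeps 1 on its own diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .synthetic import MedicineRecord

__all__ = [
    "Vocabulary",
    "FeatureMatrix",
    "SimilarityMatrix",
    "build_vocabulary",
    "vectorize",
    "cosine_similarity_matrix",
    "attach_context_features",
    "append_similarity_features",
    "NgramVectorizer",
]


@dataclass
class Vocabulary:
    """Ordered n-gram vocabulary; bigrams join words with one space."""

    entries: list
    n_range: tuple = (1, 2)

    def __post_init__(self):
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("vocabulary entries must be unique")
        self.index = {g: i for i, g in enumerate(self.entries)}

    def __len__(self):
        return len(self.entries)

    def __contains__(self, gram):
        return gram in self.index


@dataclass
class FeatureMatrix:
    """Dense documents x named-features matrix."""

    values: np.ndarray
    feature_names: list
    row_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def shape(self):
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_ids, columns=self.feature_names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


@dataclass
class SimilarityMatrix:
    """Square symmetric cosine-similarity matrix with values in [-1, 1]."""

    ids: list
    values: np.ndarray

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


def _iter_ngrams(tokens: Sequence[str], n_range: tuple):
    low, high = n_range
    for n in range(low, high + 1):
        for i in range(len(tokens) - n + 1):
            yield " ".join(tokens[i:i + n])


def build_vocabulary(
    corpus: Sequence[Sequence[str]],
    n_range: tuple = (1, 2),
    min_df: int = 1,
) -> Vocabulary:
    """All n-grams in document-frequency >= min_df, first-occurrence order."""
    if len(corpus) == 0:
        raise ValueError("corpus must be nonempty")
    order: list = []
    df: dict = {}
    for tokens in corpus:
        seen = set()
        for g in _iter_ngrams(list(tokens), n_range):
            if g not in df:
                df[g] = 0
                order.append(g)
            if g not in seen:
                df[g] += 1
                seen.add(g)
    entries = [g for g in order if df[g] >= min_df]
    return Vocabulary(entries, n_range)


def vectorize(
    corpus: Sequence[Sequence[str]],
    vocab: Vocabulary,
    tfidf: bool = False,
    row_ids: Optional[Sequence] = None,
) -> FeatureMatrix:
    """Count (or tf-idf) matrix over the vocabulary; out-of-vocabulary
    grams are ignored.

    The tf-idf weighting uses idf = ln(N / df): a gram present in every
    document gets weight zero.
    """
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    n_docs = len(corpus)
    X = np.zeros((n_docs, len(vocab)))
    for d, tokens in enumerate(corpus):
        for g in _iter_ngrams(list(tokens), vocab.n_range):
            j = vocab.index.get(g)
            if j is not None:
                X[d, j] += 1.0
    if tfidf:
        df = (X > 0).sum(axis=0)
        with np.errstate(divide="ignore"):
            idf = np.where(df > 0, np.log(n_docs / np.maximum(df, 1)), 0.0)
        X = X * idf
    if row_ids is None:
        row_ids = list(range(n_docs))
    return FeatureMatrix(X, list(vocab.entries), list(row_ids))


def cosine_similarity_matrix(X: FeatureMatrix | np.ndarray) -> SimilarityMatrix:
    """Pairwise cosine similarity; zero-norm rows are 0 against everything
    and 1 on their own diagonal."""
    if isinstance(X, FeatureMatrix):
        values, ids = X.values, X.row_ids
    else:
        values = np.asarray(X, dtype=float)
        ids = list(range(values.shape[0]))
    if values.shape[0] < 1:
        raise ValueError("need at least one row")
    norms = np.linalg.norm(values, axis=1)
    S = _sk_cosine(values)
    zero = norms == 0
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.clip(S, -1.0, 1.0, out=S)
    S = (S + S.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(ids), S)


def attach_context_features(
    X: FeatureMatrix,
    records: Sequence[MedicineRecord],
) -> FeatureMatrix:
    """Append review-percentage columns (scaled to [0,1]) and one-hot
    manufacturer columns; original columns unchanged."""
    if len(records) != X.shape[0]:
        raise ValueError("records must align with feature-matrix rows")
    triplets = np.array(
        [[r.excellent_pct, r.average_pct, r.poor_pct] for r in records])
    sums = triplets.sum(axis=1)
    bad = np.abs(sums - 100.0) > 0.5
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} record(s) have review percentages not "
            "summing to 100; rows kept as-is")
    context = triplets / 100.0
    manufacturers = sorted({r.manufacturer for r in records})
    onehot = np.zeros((len(records), len(manufacturers)))
    m_index = {m: k for k, m in enumerate(manufacturers)}
    for i, r in enumerate(records):
        onehot[i, m_index[r.manufacturer]] = 1.0
    names = list(X.feature_names) + [
        "ctx:excellent_review", "ctx:average_review", "ctx:poor_review",
    ] + [f"ctx:manufacturer={m}" for m in manufacturers]
    values = np.hstack([X.values, context, onehot])
    return FeatureMatrix(values, names, list(X.row_ids))


def append_similarity_features(X: FeatureMatrix, top_k: int = 3) -> FeatureMatrix:
    """Optionally append each document's top-k cosine similarity scores to
    other documents as features (off the default path)."""
    S = cosine_similarity_matrix(X).values.copy()
    np.fill_diagonal(S, -np.inf)
    k = min(top_k, S.shape[0] - 1)
    if k < 1:
        return X
    topk = -np.sort(-S, axis=1)[:, :k]
    topk[~np.isfinite(topk)] = 0.0
    names = list(X.feature_names) + [f"sim:top{j + 1}" for j in range(k)]
    return FeatureMatrix(
        np.hstack([X.values, topk]), names, list(X.row_ids))


class NgramVectorizer:
    """Estimator wrapper: fit learns the vocabulary, transform counts.

    Parameters mirror :func:`build_vocabulary` / :func:`vectorize`.
    """

    def __init__(self, n_range=(1, 2), min_df=1, tfidf=False):
        self.n_range = n_range
        self.min_df = min_df
        self.tfidf = tfidf

    def fit(self, X: Sequence[Sequence[str]], y=None):
        self.vocabulary_ = build_vocabulary(X, self.n_range, self.min_df)
        return self

    def transform(self, X: Sequence[Sequence[str]]) -> FeatureMatrix:
        if not hasattr(self, "vocabulary_"):
            raise RuntimeError("NgramVectorizer is not fitted")
        return vectorize(X, self.vocabulary_, tfidf=self.tfidf)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {"n_range": self.n_range, "min_df": self.min_df,
                "tfidf": self.tfidf}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
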