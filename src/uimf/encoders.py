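"""The two interchangeable document encoders.

``word_embedding`` encoder: TF-IDF statistics over the normalized corpus,
importance-ranked feature selection keeping the top 6000 terms, and either a
selected TF-IDF bag-of-words vector (default mode) or a TF-IDF-weighted mean
of word vectors (mode 2, vectors fitted in-repo by truncated SVD of the
term-document matrix or supplied externally).

``transformer`` encoder: a small trainable bidirectional self-attention
encoder over word-level token ids, mean-pooled over non-pad positions. Its
weights are trained jointly with an FCNN head inside the fusion module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import TruncatedSVD

from .nn import TransformerNet

__all__ = [
    "Vocabulary",
    "WordEmbeddingTable",
    "DocumentVectors",
    "TransformerEncoderConfig",
    "fit_tfidf",
    "rank_and_select_features",
    "encode_tfidf_bow",
    "encode_weighted_embedding",
    "TfidfBowEncoder",
    "WeightedEmbeddingEncoder",
    "TransformerDocumentEncoder",
    "init_transformer_encoder",
    "encode_transformer",
]


def _tokens(doc) -> Sequence[str]:
    return doc.tokens if hasattr(doc, "tokens") else doc


def _uid(doc, i: int) -> str:
    return doc.uid if hasattr(doc, "uid") else str(i)


@dataclass
class Vocabulary:
    """Term statistics of a fitted TF-IDF model.

    idf uses the smoothed form ln((1 + N) / (1 + df)) + 1 by default; the
    exact variant ln(N / df) + 1 is available via ``smooth=False`` at fit
    time. Column indices are contiguous over the sorted term list.
    """

    terms: list[str]
    df: np.ndarray
    idf: np.ndarray
    n_docs_fitted: int
    smooth: bool = True
    index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.terms)}
        if np.any(self.df > self.n_docs_fitted):
            raise ValueError("document frequency exceeds number of documents")
        if not np.all(np.isfinite(self.idf)):
            raise ValueError("non-finite idf")

    def __len__(self) -> int:
        return len(self.terms)

    def to_json(self) -> dict:
        return {
            "version": 1,
            "terms": self.terms,
            "df": self.df.tolist(),
            "n_docs_fitted": self.n_docs_fitted,
            "smooth": self.smooth,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Vocabulary":
        df = np.asarray(obj["df"], dtype=float)
        idf = _idf(df, obj["n_docs_fitted"], obj["smooth"])
        return cls(terms=list(obj["terms"]), df=df, idf=idf,
                   n_docs_fitted=obj["n_docs_fitted"], smooth=obj["smooth"])


def _idf(df: np.ndarray, n_docs: int, smooth: bool) -> np.ndarray:
    if smooth:
        return np.log((1.0 + n_docs) / (1.0 + df)) + 1.0
    return np.log(n_docs / df) + 1.0


def fit_tfidf(docs: Sequence, smooth: bool = True) -> Vocabulary:
    """Fit document frequencies and idf over a normalized corpus."""
    docs = list(docs)
    if len(docs) < 2:
        raise ValueError("fit_tfidf requires at least 2 documents")
    df_counts: dict[str, int] = {}
    for d in docs:
        for t in set(_tokens(d)):
            df_counts[t] = df_counts.get(t, 0) + 1
    terms = sorted(df_counts)
    df = np.array([df_counts[t] for t in terms], dtype=float)
    return Vocabulary(terms=terms, df=df, idf=_idf(df, len(docs), smooth),
                      n_docs_fitted=len(docs), smooth=smooth)


def _count_matrix(docs: Sequence, vocab: Vocabulary) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    for i, d in enumerate(docs):
        counts: dict[int, int] = {}
        for t in _tokens(d):
            j = vocab.index.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs), len(vocab)), dtype=float
    )


def rank_and_select_features(
    vocab: Vocabulary, docs: Sequence, k: int = 6000
) -> Vocabulary:
    """Keep the ``k`` most important terms, scored by summed tf-idf mass.

    Importance of a term is the sum of its tf-idf weight over the training
    documents; ties break lexicographically. The default of 6000 dimensions
    keeps the classifiers tractable on the full review corpus.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = _count_matrix(docs, vocab)
    importance = np.asarray(X.multiply(vocab.idf).sum(axis=0)).ravel()
    order = sorted(range(len(vocab)), key=lambda j: (-importance[j], vocab.terms[j]))
    keep = sorted(order[:k], key=lambda j: vocab.terms[j])
    return Vocabulary(
        terms=[vocab.terms[j] for j in keep],
        df=vocab.df[keep],
        idf=vocab.idf[keep],
        n_docs_fitted=vocab.n_docs_fitted,
        smooth=vocab.smooth,
    )


@dataclass
class DocumentVectors:
    """Encoder output: an (n_docs, dim) real matrix with provenance."""

    matrix: np.ndarray
    encoder_id: str
    uids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("DocumentVectors contains non-finite entries")
        if self.matrix.shape[0] != len(self.uids):
            raise ValueError("uids do not align with matrix rows")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.matrix)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps({"encoder_id": self.encoder_id, "uids": self.uids,
                        "dim": self.dim}),
            encoding="utf-8",
        )


def encode_tfidf_bow(docs: Sequence, vocab: Vocabulary) -> DocumentVectors:
    """tf-idf rows over the selected vocabulary, L2-normalized when nonzero."""
    docs = list(docs)
    X = _count_matrix(docs, vocab).multiply(vocab.idf).toarray()
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    X[nz] /= norms[nz]
    uids = [_uid(d, i) for i, d in enumerate(docs)]
    return DocumentVectors(matrix=X, encoder_id="word_embedding", uids=uids)


@dataclass
class WordEmbeddingTable:
    """Dense word vectors, one fixed-dimension row per term."""

    terms: list[str]
    vectors: np.ndarray
    index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if len(self.terms) == 0:
            raise ValueError("empty embedding table")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.terms)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @classmethod
    def fit_svd(
        cls, docs: Sequence, vocab: Vocabulary, d_w: int = 128, seed: int = 0
    ) -> "WordEmbeddingTable":
        """Fit word vectors by truncated SVD of the term-document tf-idf matrix."""
        X = _count_matrix(docs, vocab).multiply(vocab.idf).tocsr()
        d_w = min(d_w, min(X.shape) - 1) if min(X.shape) > 1 else 1
        svd = TruncatedSVD(n_components=d_w, random_state=seed)
        term_vectors = svd.fit_transform(X.T.tocsr())
        return cls(terms=list(vocab.terms), vectors=term_vectors)


def encode_weighted_embedding(
    docs: Sequence, vocab: Vocabulary, table: WordEmbeddingTable
) -> DocumentVectors:
    """TF-IDF-weighted mean of word vectors per document.

    v(d) = sum_t tfidf(t, d) e_t / sum_t tfidf(t, d) over the in-vocabulary
    tokens of d; a document with no covered tokens maps to the zero vector.
    """
    docs = list(docs)
    out = np.zeros((len(docs), table.dim))
    for i, d in enumerate(docs):
        weights: dict[str, float] = {}
        for t in _tokens(d):
            j = vocab.index.get(t)
            if j is not None and t in table.index:
                weights[t] = weights.get(t, 0.0) + vocab.idf[j]
        total = sum(weights.values())
        if total > 0:
            for t, w in weights.items():
                out[i] += w * table.vectors[table.index[t]]
            out[i] /= total
    uids = [_uid(d, i) for i, d in enumerate(docs)]
    return DocumentVectors(matrix=out, encoder_id="word_embedding", uids=uids)


# --- sklearn-style estimators ------------------------------------------------


class TfidfBowEncoder(BaseEstimator, TransformerMixin):
    """Selected-TF-IDF document encoder (default word-embedding encoder mode).

    Parameters
    ----------
    max_features : int, default 6000
        Number of terms kept by summed-tf-idf importance ranking.
    smooth_idf : bool, default True
        Smoothed idf ln((1+N)/(1+df)) + 1 versus exact ln(N/df) + 1.
    """

    def __init__(self, max_features: int = 6000, smooth_idf: bool = True):
        self.max_features = max_features
        self.smooth_idf = smooth_idf

    def fit(self, docs: Sequence, y=None) -> "TfidfBowEncoder":
        full = fit_tfidf(docs, smooth=self.smooth_idf)
        self.vocabulary_ = rank_and_select_features(full, docs, self.max_features)
        self.n_features_ = len(self.vocabulary_)
        return self

    def transform(self, docs: Sequence) -> np.ndarray:
        return self.encode(docs).matrix

    def encode(self, docs: Sequence) -> DocumentVectors:
        return encode_tfidf_bow(docs, self.vocabulary_)


class WeightedEmbeddingEncoder(BaseEstimator, TransformerMixin):
    """TF-IDF-weighted word-vector averaging encoder (mode 2).

    Word vectors are fitted by truncated SVD of the term-document tf-idf
    matrix unless an external :class:`WordEmbeddingTable` is supplied.
    """

    def __init__(
        self,
        d_w: int = 128,
        max_features: int = 6000,
        smooth_idf: bool = True,
        table: WordEmbeddingTable | None = None,
        seed: int = 0,
    ):
        self.d_w = d_w
        self.max_features = max_features
        self.smooth_idf = smooth_idf
        self.table = table
        self.seed = seed

    def fit(self, docs: Sequence, y=None) -> "WeightedEmbeddingEncoder":
        full = fit_tfidf(docs, smooth=self.smooth_idf)
        self.vocabulary_ = rank_and_select_features(full, docs, self.max_features)
        if self.table is not None:
            self.table_ = self.table
        else:
            self.table_ = WordEmbeddingTable.fit_svd(
                docs, self.vocabulary_, d_w=self.d_w, seed=self.seed
            )
        self.n_features_ = self.table_.dim
        return self

    def transform(self, docs: Sequence) -> np.ndarray:
        return self.encode(docs).matrix

    def encode(self, docs: Sequence) -> DocumentVectors:
        return encode_weighted_embedding(docs, self.vocabulary_, self.table_)


@dataclass(frozen=True)
class TransformerEncoderConfig:
    """Architecture of the small bidirectional transformer encoder.

    The published encoder's sizes are not public; these defaults are small
    enough to train on a CPU while keeping the standard shape (multi-head
    self-attention + feed-forward blocks with residuals and layer norm).
    """

    vocab_size: int = 4000
    d_model: int = 128
    n_heads: int = 4
    n_layers: int = 4
    feedforward_dim: int = 256
    max_sequence_length: int = 128
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model={self.d_model} must be divisible by n_heads={self.n_heads}"
            )
        if self.max_sequence_length < 8:
            raise ValueError("max_sequence_length must be >= 8")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


def init_transformer_encoder(config: TransformerEncoderConfig) -> TransformerNet:
    """Deterministically initialize the encoder network from a config."""
    return TransformerNet(
        vocab_size=config.vocab_size,
        d_model=config.d_model,
        n_heads=config.n_heads,
        n_layers=config.n_layers,
        d_ff=config.feedforward_dim,
        max_len=config.max_sequence_length,
        seed=config.seed,
    )


class TransformerDocumentEncoder(BaseEstimator, TransformerMixin):
    """Trainable bidirectional transformer document encoder.

    ``fit`` builds the word-level tokenizer and initializes the network;
    the weights are trained jointly with an FCNN head by the fusion module.
    ``transform`` returns mean-over-non-pad pooled vectors.
    """

    PAD, UNK = 0, 1

    def __init__(self, config: TransformerEncoderConfig | None = None):
        self.config = config

    def fit(self, docs: Sequence, y=None) -> "TransformerDocumentEncoder":
        cfg = self.config or TransformerEncoderConfig()
        freq: dict[str, int] = {}
        for d in docs:
            for t in _tokens(d):
                freq[t] = freq.get(t, 0) + 1
        ranked = sorted(freq, key=lambda t: (-freq[t], t))
        capacity = cfg.vocab_size - 2
        self.token_index_ = {t: i + 2 for i, t in enumerate(ranked[:capacity])}
        self.config_ = cfg
        self.network_ = init_transformer_encoder(cfg)
        self.n_features_ = cfg.d_model
        self.n_truncated_ = 0
        return self

    def encode_ids(self, docs: Sequence) -> tuple[np.ndarray, np.ndarray]:
        """Token ids and 0/1 pad mask, truncated at max_sequence_length."""
        max_len = self.config_.max_sequence_length
        batch_len = max(
            1, min(max_len, max(len(_tokens(d)) for d in docs))
        )
        ids = np.full((len(docs), batch_len), self.PAD, dtype=np.int64)
        mask = np.zeros((len(docs), batch_len))
        for i, d in enumerate(docs):
            toks = list(_tokens(d))
            if len(toks) > max_len:
                self.n_truncated_ += 1
                toks = toks[:max_len]
            for j, t in enumerate(toks):
                ids[i, j] = self.token_index_.get(t, self.UNK)
                mask[i, j] = 1.0
        return ids, mask

    def transform(self, docs: Sequence) -> np.ndarray:
        return self.encode(docs).matrix

    def encode(self, docs: Sequence, batch_size: int = 64) -> DocumentVectors:
        docs = list(docs)
        chunks = []
        for start in range(0, len(docs), batch_size):
            batch = docs[start : start + batch_size]
            ids, mask = self.encode_ids(batch)
            chunks.append(self.network_(ids, mask).data)
        uids = [_uid(d, i) for i, d in enumerate(docs)]
        return DocumentVectors(
            matrix=np.vstack(chunks), encoder_id="transformer", uids=uids
        )


def encode_transformer(
    docs: Sequence, encoder: TransformerDocumentEncoder
) -> DocumentVectors:
    """Functional alias for :meth:`TransformerDocumentEncoder.encode`."""
    return encoder.encode(docs)
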