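"""TF-IDF statistics, feature selection, embedding averaging, transformer."""

import math

import numpy as np
import pytest
from sklearn.feature_extraction.text import TfidfVectorizer

from uimf.encoders import (
    TfidfBowEncoder,
    TransformerDocumentEncoder,
    TransformerEncoderConfig,
    WeightedEmbeddingEncoder,
    WordEmbeddingTable,
    encode_tfidf_bow,
    encode_weighted_embedding,
    fit_tfidf,
    init_transformer_encoder,
    rank_and_select_features,
)
from uimf.preprocess import LabeledDocument


def docs_from_strings(texts):
    return [
        LabeledDocument(uid=str(i), tokens=tuple(t.split()), label=0)
        for i, t in enumerate(texts)
    ]


class TestFitTfidf:
    def test_two_doc_hand_example(self):
        vocab = fit_tfidf(docs_from_strings(["a b", "a"]))
        assert vocab.terms == ["a", "b"]
        np.testing.assert_allclose(vocab.df, [2, 1])
        assert vocab.idf[0] == pytest.approx(math.log(3 / 3) + 1)
        assert vocab.idf[1] == pytest.approx(math.log(3 / 2) + 1)

    def test_ubiquitous_term_has_minimal_idf(self):
        vocab = fit_tfidf(docs_from_strings(["a b", "a c", "a d"]))
        a = vocab.idf[vocab.index["a"]]
        assert a == min(vocab.idf)

    def test_idf_matches_sklearn_smooth_variant(self):
        texts = ["day feel better", "day worse sleep", "feel sleep day better day"]
        vocab = fit_tfidf(docs_from_strings(texts))
        sk = TfidfVectorizer(smooth_idf=True, norm=None).fit(texts)
        for term, idx in sk.vocabulary_.items():
            assert vocab.idf[vocab.index[term]] == pytest.approx(sk.idf_[idx])

    def test_refit_deterministic(self):
        docs = docs_from_strings(["a b c", "b c d", "d e"])
        v1, v2 = fit_tfidf(docs), fit_tfidf(docs)
        assert v1.terms == v2.terms
        np.testing.assert_array_equal(v1.idf, v2.idf)

    def test_single_doc_rejected(self):
        with pytest.raises(ValueError):
            fit_tfidf(docs_from_strings(["a"]))


class TestFeatureSelection:
    def test_k_ge_vocab_is_identity(self):
        docs = docs_from_strings(["a b c", "b c d"])
        vocab = fit_tfidf(docs)
        reduced = rank_and_select_features(vocab, docs, k=100)
        assert reduced.terms == vocab.terms

    def test_k1_picks_max_summed_tfidf(self):
        docs = docs_from_strings(["a a a b", "a a c", "b c"])
        vocab = fit_tfidf(docs)
        # brute-force score per term: sum over docs of tf * idf
        scores = {}
        for t in vocab.terms:
            idf = vocab.idf[vocab.index[t]]
            scores[t] = sum(d.tokens.count(t) * idf for d in docs)
        best = max(sorted(scores), key=lambda t: scores[t])
        reduced = rank_and_select_features(vocab, docs, k=1)
        assert reduced.terms == [best]

    def test_default_k_is_6000(self):
        assert TfidfBowEncoder().max_features == 6000

    def test_selection_then_encode_equals_full_when_k_is_vocab(self):
        docs = docs_from_strings(["a b c d", "b c", "a d d"])
        vocab = fit_tfidf(docs)
        full = encode_tfidf_bow(docs, vocab)
        reduced = rank_and_select_features(vocab, docs, k=len(vocab))
        again = encode_tfidf_bow(docs, reduced)
        np.testing.assert_allclose(full.matrix, again.matrix)


class TestEncodeTfidfBow:
    def test_rows_unit_or_zero_norm(self):
        docs = docs_from_strings(["a b c", "b c", "z z"])
        vocab = fit_tfidf(docs_from_strings(["a b c", "b c"]))
        vectors = encode_tfidf_bow(docs, vocab)
        norms = np.linalg.norm(vectors.matrix, axis=1)
        for n in norms:
            assert n == pytest.approx(0.0, abs=1e-9) or n == pytest.approx(1.0, abs=1e-9)

    def test_oov_document_is_zero_row(self):
        vocab = fit_tfidf(docs_from_strings(["a b", "b c"]))
        vectors = encode_tfidf_bow(docs_from_strings(["zzz qqq"]), vocab)
        assert np.all(vectors.matrix == 0)

    def test_single_term_document_is_unit(self):
        vocab = fit_tfidf(docs_from_strings(["a b", "a c"]))
        vectors = encode_tfidf_bow(docs_from_strings(["a"]), vocab)
        assert vectors.matrix[0, vocab.index["a"]] == pytest.approx(1.0)

    def test_two_doc_matrix_matches_hand_tfidf(self):
        docs = docs_from_strings(["a a b", "b"])
        vocab = fit_tfidf(docs)
        raw = np.array(
            [
                [2 * vocab.idf[0], 1 * vocab.idf[1]],
                [0.0, 1 * vocab.idf[1]],
            ]
        )
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        np.testing.assert_allclose(encode_tfidf_bow(docs, vocab).matrix, raw)


class TestWeightedEmbedding:
    def _table(self):
        return WordEmbeddingTable(
            terms=["a", "b", "c"],
            vectors=np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        )

    def test_single_word_doc_is_that_vector(self):
        docs = docs_from_strings(["a b", "b c"])
        vocab = fit_tfidf(docs)
        out = encode_weighted_embedding(docs_from_strings(["b"]), vocab, self._table())
        np.testing.assert_allclose(out.matrix[0], [0.0, 1.0])

    def test_equal_weights_is_plain_mean(self):
        docs = docs_from_strings(["a b", "a b", "a b"])  # df equal -> idf equal
        vocab = fit_tfidf(docs)
        out = encode_weighted_embedding(docs_from_strings(["a b"]), vocab, self._table())
        np.testing.assert_allclose(out.matrix[0], [0.5, 0.5])

    def test_three_word_weighted_mean_hand_computed(self):
        docs = docs_from_strings(["a b c", "a b", "a"])
        vocab = fit_tfidf(docs)
        idf = {t: vocab.idf[vocab.index[t]] for t in "abc"}
        table = self._table()
        total = idf["a"] + idf["b"] + idf["c"]
        expected = (
            idf["a"] * np.array([1.0, 0]) + idf["b"] * np.array([0, 1.0])
            + idf["c"] * np.array([1.0, 1.0])
        ) / total
        out = encode_weighted_embedding(docs_from_strings(["a b c"]), vocab, table)
        np.testing.assert_allclose(out.matrix[0], expected)

    def test_output_inside_convex_hull(self):
        rng = np.random.default_rng(0)
        table = WordEmbeddingTable(
            terms=list("abcdef"), vectors=rng.normal(size=(6, 4))
        )
        docs = docs_from_strings(["a b c d", "b e f", "c d e", "a f"])
        vocab = fit_tfidf(docs)
        out = encode_weighted_embedding(docs, vocab, table)
        for d, row in zip(docs, out.matrix):
            used = [table.vectors[table.index[t]] for t in set(d.tokens)]
            lo, hi = np.min(used, axis=0), np.max(used, axis=0)
            assert np.all(row >= lo - 1e-9) and np.all(row <= hi + 1e-9)

    def test_svd_table_covers_vocabulary(self, small_corpus):
        enc = WeightedEmbeddingEncoder(d_w=8, max_features=100).fit(small_corpus)
        assert enc.table_.vectors.shape[1] == 8
        assert set(enc.table_.terms) == set(enc.vocabulary_.terms)


class TestTransformerEncoder:
    CFG = TransformerEncoderConfig(
        vocab_size=200, d_model=16, n_heads=2, n_layers=1,
        feedforward_dim=32, max_sequence_length=16, seed=0,
    )

    def test_same_seed_identical_parameters(self):
        a = init_transformer_encoder(self.CFG)
        b = init_transformer_encoder(self.CFG)
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TransformerEncoderConfig(d_model=10, n_heads=4)
        with pytest.raises(ValueError):
            TransformerEncoderConfig(n_layers=0)
        with pytest.raises(ValueError):
            TransformerEncoderConfig(max_sequence_length=4)

    def _fitted(self, docs):
        enc = TransformerDocumentEncoder(config=self.CFG)
        return enc.fit(docs)

    def test_output_shape_is_d_model(self, small_corpus):
        enc = self._fitted(small_corpus[:20])
        out = enc.transform(small_corpus[:5])
        assert out.shape == (5, self.CFG.d_model)

    def test_pad_invariance(self, small_corpus):
        docs = small_corpus[:6]
        enc = self._fitted(docs)
        short, longer = docs[0], docs[1]
        alone = enc.transform([short])[0]        # padded only to its own length
        batched = enc.transform([short, longer])[0]  # padded to the batch max
        np.testing.assert_allclose(alone, batched, atol=1e-10)

    def test_identical_documents_identical_rows(self, small_corpus):
        enc = self._fitted(small_corpus[:10])
        out = enc.transform([small_corpus[0], small_corpus[0]])
        np.testing.assert_array_equal(out[0], out[1])

    def test_permutation_consistency(self, small_corpus):
        docs = small_corpus[:8]
        enc = self._fitted(docs)
        base = enc.transform(docs)
        perm = [3, 0, 7, 1, 5, 2, 6, 4]
        shuffled = enc.transform([docs[i] for i in perm])
        np.testing.assert_allclose(shuffled, base[perm], atol=1e-10)

    def test_truncation_counted(self, small_corpus):
        cfg = TransformerEncoderConfig(
            vocab_size=200, d_model=16, n_heads=2, n_layers=1,
            feedforward_dim=32, max_sequence_length=8, seed=0,
        )
        enc = TransformerDocumentEncoder(config=cfg).fit(small_corpus[:20])
        long_docs = [d for d in small_corpus[:20] if len(d.tokens) > 8]
        enc.transform(long_docs)
        assert enc.n_truncated_ == len(long_docs)
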