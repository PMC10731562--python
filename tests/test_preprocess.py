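"""Ingestion, text normalization, label mapping and splitting."""

import itertools
from collections import Counter

import edlib
import numpy as np
import pytest

from uimf.preprocess import (
    DEFAULT_CONDITIONS,
    NormalizeOptions,
    ReviewRecord,
    SpellingModel,
    SplitSpec,
    convert_chat_words,
    convert_emoticons,
    correct_spelling,
    edit_candidates,
    filter_conditions,
    map_score_to_class,
    normalize_corpus,
    normalize_document,
    read_reviews,
    stratified_split,
    top_frequent_words,
)


class TestReadReviews:
    def test_reads_all_rows_with_scores(self, table1_csv):
        records, report = read_reviews(table1_csv)
        assert len(records) == 3
        assert report.total_skipped == 0
        assert records[0].score == 9
        assert records[0].drug_name == "Valsartan"
        assert "no side effect" in records[0].review_text

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("uniqueID,drugName,condition,review,score\n")
        records, report = read_reviews(p)
        assert records == [] and report.total_skipped == 0

    def test_bad_rows_are_dropped_and_counted(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "uniqueID,drugName,condition,review,score\n"
            "1,a,depression,fine,abc\n"
            "2,a,depression,fine,42\n"
            "3,a,depression,,5\n"
            "4,a,depression,good,5\n"
        )
        records, report = read_reviews(p)
        assert [r.uid for r in records] == ["4"]
        assert report.unparsable_score == 1
        assert report.out_of_range_score == 1
        assert report.empty_review == 1

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "noscore.csv"
        p.write_text("uniqueID,drugName,condition,review\n")
        with pytest.raises(ValueError, match="score"):
            read_reviews(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_reviews(tmp_path / "nope.csv")


class TestFilterConditions:
    def test_default_whitelist_keeps_only_mental_health(self, table1_csv):
        records, _ = read_reviews(table1_csv)
        kept = filter_conditions(records)
        assert [r.condition for r in kept] == ["Depression"]

    def test_case_insensitive_match(self):
        r = ReviewRecord("1", "x", "Depression", "text", 5)
        assert filter_conditions([r], {"depression"}) == [r]

    def test_whitelist_of_all_conditions_is_identity(self, table1_csv):
        records, _ = read_reviews(table1_csv)
        assert filter_conditions(records, {r.condition for r in records}) == records

    def test_bundled_list_has_21_names(self):
        assert len(DEFAULT_CONDITIONS) == 21
        assert "insomnia" in DEFAULT_CONDITIONS


class TestConversions:
    def test_no_emoticon_unchanged(self, maps):
        assert convert_emoticons("no emoticons here.", maps) == "no emoticons here."

    def test_emoticon_replaced_by_gloss(self, maps):
        out = convert_emoticons("I feel better :)", maps)
        assert out == "I feel better " + maps.emoticon_map[":)"]

    def test_longest_emoticon_wins(self, maps):
        assert convert_emoticons(":))", maps) == maps.emoticon_map[":))"]

    def test_chat_word_expanded(self, maps):
        out = convert_chat_words("idk if it works", maps)
        assert out == maps.chatword_map["idk"] + " if it works"

    def test_chat_word_case_insensitive(self, maps):
        assert maps.chatword_map["idk"] in convert_chat_words("IDK!", maps)

    def test_substring_inside_word_untouched(self, maps):
        assert convert_chat_words("kidknapping", maps) == "kidknapping"

    def test_conversion_idempotent_on_noisy_corpus(self, maps, noisy_records):
        for r in noisy_records:
            once = convert_chat_words(convert_emoticons(r.review_text, maps), maps)
            twice = convert_chat_words(convert_emoticons(once, maps), maps)
            assert once == twice


class TestSpelling:
    def test_candidates_contain_word_itself(self):
        for w in ("at", "spelling", "medication"):
            assert w in edit_candidates(w, 1)
            assert w in edit_candidates(w, 2)

    def test_speling_distance1_contains_spelling(self):
        assert "spelling" in edit_candidates("speling", 1)

    def test_distance1_set_matches_damerau_enumeration(self):
        # brute force: every string of length 1..3 over a-z within restricted
        # Damerau-Levenshtein distance 1 of "at" (edits include transposition)
        def damerau(a, b):
            d = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
            for i in range(len(a) + 1):
                d[i][0] = i
            for j in range(len(b) + 1):
                d[0][j] = j
            for i in range(1, len(a) + 1):
                for j in range(1, len(b) + 1):
                    cost = a[i - 1] != b[j - 1]
                    d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1,
                                  d[i - 1][j - 1] + cost)
                    if (i > 1 and j > 1 and a[i - 1] == b[j - 2]
                            and a[i - 2] == b[j - 1]):
                        d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
            return d[-1][-1]

        letters = "abcdefghijklmnopqrstuvwxyz"
        universe = [
            "".join(t)
            for n in (1, 2, 3)
            for t in itertools.product(letters, repeat=n)
        ]
        oracle = {s for s in universe if damerau("at", s) <= 1}
        assert edit_candidates("at", 1) == oracle

    def test_non_alphabetic_rejected(self):
        with pytest.raises(ValueError):
            edit_candidates("b4", 1)

    def test_known_word_unchanged(self):
        model = SpellingModel({"spelling": 3, "hello": 5})
        assert correct_spelling("hello", model) == "hello"

    def test_distance1_correction(self):
        model = SpellingModel({"spelling": 1})
        assert correct_spelling("speling", model) == "spelling"

    def test_distance2_fallback_then_passthrough(self):
        model = SpellingModel({"spelling": 1})
        assert correct_spelling("spelin", model) == "spelling"  # distance 2
        assert correct_spelling("xyzzyqq", model) == "xyzzyqq"  # no candidate

    def test_ties_break_lexicographically(self):
        model = SpellingModel({"cat": 2, "bat": 2})
        assert correct_spelling("aat", model) == "bat"

    def test_correction_never_increases_distance_to_known_words(self):
        rng = np.random.default_rng(3)
        vocab = ["medication", "anxiety", "doctor", "sleeping", "helped",
                 "week", "month", "effect", "better", "depression"]
        model = SpellingModel({w: 5 for w in vocab})

        def nearest(word):
            return min(
                edlib.align(word, v, task="distance")["editDistance"] for v in vocab
            )

        letters = "abcdefghijklmnopqrstuvwxyz"
        for _ in range(100):
            base = vocab[rng.integers(len(vocab))]
            i = int(rng.integers(len(base)))
            word = base[:i] + letters[rng.integers(26)] + base[i + 1:]
            corrected = correct_spelling(word, model)
            assert nearest(corrected) <= nearest(word)


class TestLabelMapping:
    @pytest.mark.parametrize(
        "score,expected",
        [(1, 0), (4, 0), (5, 1), (8, 1), (9, 2), (10, 2), (2, 0), (6, 1)],
    )
    def test_score_ranges(self, score, expected):
        assert map_score_to_class(score) == expected

    def test_total_surjective_monotone(self):
        values = [map_score_to_class(s) for s in range(1, 11)]
        assert set(values) == {0, 1, 2}
        assert values == sorted(values)

    @pytest.mark.parametrize("score", [0, 11, -3])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError):
            map_score_to_class(score)


class TestNormalizeDocument:
    def test_clean_text_score9_label2(self, maps):
        r = ReviewRecord("1", "x", "depression", "This Medication Helped Greatly", 9)
        doc = normalize_document(r, maps)
        assert doc.label == 2
        assert all(t == t.lower() for t in doc.tokens)
        assert "medication" in doc.tokens

    def test_only_emoticon_and_stopwords_flagged_empty(self, maps):
        r = ReviewRecord("1", "x", "depression", ":) the and of", 5)
        # the gloss words are themselves informative, so strip them too
        opts = NormalizeOptions(
            stopwords=frozenset(
                {"the", "and", "of", "happy", "face", "smiley"}
            )
        )
        assert normalize_document(r, maps, options=opts) is None

    def test_stopword_flag_off_retains_stopwords(self, maps):
        r = ReviewRecord("1", "x", "depression", "it is the best", 9)
        doc = normalize_document(r, maps, options=NormalizeOptions(remove_stopwords=False))
        assert "the" in doc.tokens

    def test_grammar_hook_is_applied(self, maps):
        r = ReviewRecord("1", "x", "depression", "feeling fine", 9)
        doc = normalize_document(
            r, maps,
            options=NormalizeOptions(grammar_hook=lambda t: t + " appended"),
        )
        assert "appended" in doc.tokens


class TestStratifiedSplit:
    def _docs(self, per_class):
        from conftest import make_docs
        return make_docs(per_class)

    def test_exact_63_7_30_at_100_per_class(self):
        docs = self._docs(100)
        split = stratified_split(docs, SplitSpec(seed=0))
        for part, n in ((split.train, 189), (split.validation, 21), (split.test, 90)):
            assert len(part) == n
        by_label = lambda part, lab: sum(1 for d in docs if d.uid in part and d.label == lab)
        for lab in (0, 1, 2):
            assert by_label(split.train, lab) == 63
            assert by_label(split.validation, lab) == 7
            assert by_label(split.test, lab) == 30

    def test_same_seed_reproduces_split(self):
        docs = self._docs(40)
        a = stratified_split(docs, SplitSpec(seed=5))
        b = stratified_split(docs, SplitSpec(seed=5))
        assert a.train == b.train and a.validation == b.validation and a.test == b.test
        assert a.folds == b.folds

    def test_folds_partition_train_union_validation(self):
        docs = self._docs(40)
        split = stratified_split(docs, SplitSpec(seed=1))
        union = set().union(*split.folds)
        assert union == split.train | split.validation
        assert sum(len(f) for f in split.folds) == len(union)  # pairwise disjoint

    def test_parts_disjoint_and_exhaustive(self):
        docs = self._docs(17)
        split = stratified_split(docs, SplitSpec(seed=2))
        assert not (split.train & split.validation)
        assert not (split.train & split.test)
        assert not (split.validation & split.test)
        assert split.train | split.validation | split.test == {d.uid for d in docs}

    def test_per_class_deviation_at_most_one(self):
        docs = self._docs(23)
        split = stratified_split(docs, SplitSpec(seed=3))
        for lab in (0, 1, 2):
            n = 23
            for part, frac in ((split.train, 0.63), (split.validation, 0.07), (split.test, 0.30)):
                got = sum(1 for d in docs if d.uid in part and d.label == lab)
                assert abs(got - n * frac) <= 1

    def test_small_class_rejected(self):
        from conftest import make_docs
        docs = make_docs(5)
        with pytest.raises(ValueError, match="fewer than"):
            stratified_split(docs, SplitSpec(n_folds=10, seed=0))


class TestTopFrequentWords:
    def test_matches_counter_oracle_on_fixture(self, small_corpus):
        docs = small_corpus[:20]
        counts = Counter(t for d in docs for t in d.tokens)
        oracle = [t for t, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))][:10]
        assert top_frequent_words(docs, 10) == oracle

    def test_k_larger_than_vocab_returns_all(self, small_corpus):
        docs = small_corpus[:5]
        vocab = {t for d in docs for t in d.tokens}
        assert len(top_frequent_words(docs, 10_000)) == len(vocab)

    def test_invalid_k(self, small_corpus):
        with pytest.raises(ValueError):
            top_frequent_words(small_corpus, 0)

    def test_per_class_filter(self, small_corpus):
        ranked0 = top_frequent_words(small_corpus, 30, label=0)
        assert len(ranked0) == 30
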