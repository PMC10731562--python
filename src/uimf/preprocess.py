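"""Corpus ingestion and normalization for noisy patient-written drug reviews.

Patient reviews mix clinical vocabulary with chat slang, emoticons and
misspellings. The pipeline here reads the delimiter-separated review schema
(unique id, drug name, condition, review text, integer score 1-10), normalizes
the text (emoticon glossing, chat-word expansion, Norvig-style spelling
correction), maps the 10-point score onto three satisfaction classes
(poor / fair / good), and produces stratified train/validation/test splits
plus cross-validation folds.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

__all__ = [
    "ReviewRecord",
    "NormalizationMaps",
    "SpellingModel",
    "LabeledDocument",
    "SplitSpec",
    "DatasetSplit",
    "SkipReport",
    "NormalizeOptions",
    "DEFAULT_CONDITIONS",
    "load_default_maps",
    "read_reviews",
    "filter_conditions",
    "convert_emoticons",
    "convert_chat_words",
    "edit_candidates",
    "correct_spelling",
    "map_score_to_class",
    "tokenize",
    "normalize_document",
    "normalize_corpus",
    "stratified_split",
    "top_frequent_words",
    "write_normalized_corpus",
    "read_normalized_corpus",
]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

#: The 21 condition names bundled as the default whitelist: 19 mental
#: disorders, performance anxiety, and insomnia (which frequently co-occurs
#: with mental-disorder diagnoses).
DEFAULT_CONDITIONS: tuple[str, ...] = (
    "bipolar disorder",
    "depression",
    "panic disorder",
    "psychosis",
    "schizophrenia",
    "anxiety",
    "major depressive disorder",
    "obsessive compulsive disorder",
    "generalized anxiety disorder",
    "autism spectrum disorder",
    "paranoid disorder",
    "performance anxiety",
    "schizoaffective disorder",
    "agitated depression",
    "social anxiety disorder",
    "postpartum depression",
    "dissociative identity disorder",
    "persistent depressive disorder",
    "intermittent explosive disorder",
    "hyperekplexia",
    "insomnia",
)


@dataclass(frozen=True)
class ReviewRecord:
    """One patient review with its 1-10 satisfaction score."""

    uid: str
    drug_name: str
    condition: str
    review_text: str
    score: int

    def __post_init__(self) -> None:
        if not (1 <= int(self.score) <= 10):
            raise ValueError(f"score must be in [1, 10], got {self.score}")
        if not self.review_text.strip():
            raise ValueError("review_text empty after whitespace stripping")


@dataclass(frozen=True)
class NormalizationMaps:
    """Emoticon -> gloss and slang-token -> expansion dictionaries.

    Emoticon lookup is case-sensitive; chat-word lookup is case-insensitive.
    Glosses and expansions never contain map keys, which makes conversion
    idempotent.
    """

    emoticon_map: dict[str, str]
    chatword_map: dict[str, str]

    def __post_init__(self) -> None:
        lowered = [k.lower() for k in self.chatword_map]
        if len(set(lowered)) != len(lowered):
            raise ValueError("chatword_map keys collide case-insensitively")
        for gloss in self.emoticon_map.values():
            for key in self.emoticon_map:
                if key in gloss:
                    raise ValueError(f"gloss {gloss!r} contains emoticon key {key!r}")
        chat_keys = {k.lower() for k in self.chatword_map}
        for expansion in self.chatword_map.values():
            for tok in _token_pattern.findall(expansion.lower()):
                if tok in chat_keys:
                    raise ValueError(
                        f"expansion {expansion!r} contains chat-word key {tok!r}"
                    )


def load_default_maps() -> NormalizationMaps:
    """Load the bundled emoticon and chat-word dictionaries."""
    data = resources.files("uimf") / "data"
    emo = json.loads((data / "emoticons.json").read_text(encoding="utf-8"))
    chat = json.loads((data / "chatwords.json").read_text(encoding="utf-8"))
    return NormalizationMaps(emoticon_map=emo["map"], chatword_map=chat["map"])


@dataclass
class SkipReport:
    """Counts of rows dropped or flagged during ingestion/normalization."""

    unparsable_score: int = 0
    out_of_range_score: int = 0
    empty_review: int = 0
    empty_after_normalization: int = 0
    truncated: int = 0

    @property
    def total_skipped(self) -> int:
        return (
            self.unparsable_score
            + self.out_of_range_score
            + self.empty_review
            + self.empty_after_normalization
        )

    def to_json(self) -> dict:
        return {
            "unparsable_score": self.unparsable_score,
            "out_of_range_score": self.out_of_range_score,
            "empty_review": self.empty_review,
            "empty_after_normalization": self.empty_after_normalization,
            "total_skipped": self.total_skipped,
        }


_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "uid": ("uid", "uniqueid", "unique_id", "id", "patientid", "patient_id"),
    "drug_name": ("drug_name", "drugname", "drug"),
    "condition": ("condition", "illness", "disorder"),
    "review_text": ("review_text", "review", "text", "comment"),
    "score": ("score", "rating", "usefulcount_score"),
}


def _canon(name: str) -> str:
    return re.sub(r"[^a-z0-9_]", "", name.strip().lower().replace(" ", "_"))


def read_reviews(
    path: str | Path,
    dialect: str | None = None,
    column_aliases: dict[str, tuple[str, ...]] | None = None,
) -> tuple[list[ReviewRecord], SkipReport]:
    """Read a delimiter-separated review file into :class:`ReviewRecord` rows.

    Parameters
    ----------
    path
        UTF-8 text file with a header row.
    dialect
        Field delimiter. ``None`` infers tab for ``.tsv`` files, comma
        otherwise.
    column_aliases
        Optional override of the accepted header names per canonical column.

    Returns
    -------
    records, skip_report
        Rows with an unparsable/out-of-range score or an empty review are
        dropped and counted in the skip report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = dialect if dialect is not None else ("\t" if path.suffix == ".tsv" else ",")
    aliases = column_aliases or _COLUMN_ALIASES

    records: list[ReviewRecord] = []
    report = SkipReport()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, no header row") from None
        canon_header = [_canon(h) for h in header]
        col_idx: dict[str, int] = {}
        for canonical, names in aliases.items():
            for i, h in enumerate(canon_header):
                if h in names:
                    col_idx[canonical] = i
                    break
            else:
                raise ValueError(
                    f"{path}: missing mandatory column {canonical!r} "
                    f"(accepted names: {', '.join(names)})"
                )
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            raw_score = row[col_idx["score"]].strip().replace(",", "")
            try:
                score = int(float(raw_score))
            except ValueError:
                report.unparsable_score += 1
                continue
            if not (1 <= score <= 10):
                report.out_of_range_score += 1
                continue
            text = row[col_idx["review_text"]]
            if not text.strip():
                report.empty_review += 1
                continue
            records.append(
                ReviewRecord(
                    uid=row[col_idx["uid"]].strip().replace(",", ""),
                    drug_name=row[col_idx["drug_name"]].strip(),
                    condition=row[col_idx["condition"]].strip(),
                    review_text=text,
                    score=score,
                )
            )
    return records, report


def filter_conditions(
    records: Iterable[ReviewRecord],
    condition_whitelist: Iterable[str] = DEFAULT_CONDITIONS,
) -> list[ReviewRecord]:
    """Keep records whose condition matches the whitelist.

    Matching is case-insensitive exact match after collapsing internal
    whitespace. The bundled default is the 21-name mental-health list.
    """
    whitelist = {" ".join(c.split()).lower() for c in condition_whitelist}
    if not whitelist:
        raise ValueError("condition whitelist must be non-empty")
    return [
        r for r in records if " ".join(r.condition.split()).lower() in whitelist
    ]


# --- text normalization ------------------------------------------------------

_token_pattern = re.compile(r"[a-z0-9]+(?:[/'][a-z0-9]+)*")


def _emoticon_regex(maps: NormalizationMaps) -> re.Pattern:
    keys = sorted(maps.emoticon_map, key=len, reverse=True)
    return re.compile("|".join(re.escape(k) for k in keys))


def convert_emoticons(text: str, maps: NormalizationMaps) -> str:
    """Replace every maximal emoticon occurrence by its textual gloss.

    Longest emoticons match first (``:))`` before ``:)``); surrounding text is
    untouched and the operation is idempotent because glosses contain no
    emoticon keys.
    """
    pattern = _emoticon_regex(maps)
    return pattern.sub(lambda m: maps.emoticon_map[m.group(0)], text)


_chat_token_pattern = re.compile(r"[A-Za-z0-9]+(?:[/'][A-Za-z0-9]+)*")


def convert_chat_words(text: str, maps: NormalizationMaps) -> str:
    """Expand slang tokens (whole-token, case-insensitive) to standard text.

    Substrings inside longer words are never touched: ``idk`` expands, but
    ``kidknapping`` is left alone.
    """
    lower_map = {k.lower(): v for k, v in maps.chatword_map.items()}

    def repl(m: re.Match) -> str:
        return lower_map.get(m.group(0).lower(), m.group(0))

    return _chat_token_pattern.sub(repl, text)


# --- spelling correction -----------------------------------------------------


def edit_candidates(word: str, max_distance: int = 1) -> set[str]:
    """All strings within ``max_distance`` single-character edits of ``word``.

    Edits are deletion, adjacent transposition, replacement and insertion over
    a-z. The returned set always contains ``word`` itself.
    """
    if not word or not word.isalpha() or not word.islower():
        raise ValueError(f"word must be lowercase alphabetic, got {word!r}")
    if max_distance not in (1, 2):
        raise ValueError("max_distance must be 1 or 2")

    def edits1(w: str) -> set[str]:
        splits = [(w[:i], w[i:]) for i in range(len(w) + 1)]
        deletes = {L + R[1:] for L, R in splits if R}
        transposes = {L + R[1] + R[0] + R[2:] for L, R in splits if len(R) > 1}
        replaces = {L + c + R[1:] for L, R in splits if R for c in _ALPHABET}
        inserts = {L + c + R for L, R in splits for c in _ALPHABET}
        return deletes | transposes | replaces | inserts

    out = {word} | edits1(word)
    if max_distance == 2:
        out |= {e2 for e1 in edits1(word) for e2 in edits1(e1)}
    return out


@dataclass
class SpellingModel:
    """Unigram language model backing the Norvig-style spelling corrector."""

    unigram_counts: dict[str, int] = field(default_factory=dict)
    _correction_cache: dict[str, str] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def total_count(self) -> int:
        return sum(self.unigram_counts.values())

    @classmethod
    def fit(cls, token_stream: Iterable[str]) -> "SpellingModel":
        counts = Counter(t for t in token_stream if t.isalpha())
        return cls(unigram_counts=dict(counts))

    def known(self, words: Iterable[str]) -> set[str]:
        return {w for w in words if w in self.unigram_counts}

    def probability(self, word: str) -> float:
        total = self.total_count
        return self.unigram_counts.get(word, 0) / total if total else 0.0


def correct_spelling(word: str, model: SpellingModel) -> str:
    """Correct ``word`` to the most probable known candidate.

    Known words pass through; otherwise the highest-unigram-probability known
    candidate at edit distance 1 wins, then distance 2, and with no known
    candidate at all the word is returned unchanged. Probability ties break
    lexicographically.
    """
    if word in model.unigram_counts:
        return word
    cached = model._correction_cache.get(word)
    if cached is not None:
        return cached
    corrected = word
    for distance in (1, 2):
        candidates = model.known(edit_candidates(word, distance))
        if candidates:
            corrected = max(sorted(candidates), key=model.probability)
            break
    model._correction_cache[word] = corrected
    return corrected


# `max` keeps the first maximal element of the sorted candidates, so ties on
# probability resolve to the lexicographically smallest word.


def map_score_to_class(score: int) -> int:
    """Map a 1-10 satisfaction score onto {0: poor, 1: fair, 2: good}.

    Scores 1-4 are poor (urgent re-diagnosis), 5-8 fair (monitor the case),
    9-10 good (no further action).
    """
    if not (1 <= int(score) <= 10):
        raise ValueError(f"score must be in [1, 10], got {score}")
    score = int(score)
    if score <= 4:
        return 0
    if score <= 8:
        return 1
    return 2


@dataclass(frozen=True)
class LabeledDocument:
    """A normalized, tokenized review with its 3-class label."""

    uid: str
    tokens: tuple[str, ...]
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1, 2):
            raise ValueError(f"label must be in {{0,1,2}}, got {self.label}")


@dataclass
class NormalizeOptions:
    """Switches for :func:`normalize_document`.

    ``grammar_hook`` is a pluggable text -> text callable applied after slang
    expansion; the default is a no-op (external grammar-correction services
    are out of scope).
    """

    remove_stopwords: bool = True
    correct_spelling: bool = True
    grammar_hook: Callable[[str], str] | None = None
    stopwords: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumerics, dropping empty tokens."""
    return re.findall(r"[a-z0-9]+", text.lower())


def normalize_document(
    record: ReviewRecord,
    maps: NormalizationMaps,
    model: SpellingModel | None = None,
    options: NormalizeOptions | None = None,
) -> LabeledDocument | None:
    """Run the full normalization pipeline on one review.

    Fixed order: emoticon glossing -> chat-word expansion -> grammar hook ->
    spelling correction -> lowercasing/tokenization -> optional stop-word
    removal. Returns ``None`` when no tokens survive (caller counts these).
    """
    options = options or NormalizeOptions()
    text = convert_emoticons(record.review_text, maps)
    text = convert_chat_words(text, maps)
    if options.grammar_hook is not None:
        text = options.grammar_hook(text)
    tokens = tokenize(text)
    if options.correct_spelling and model is not None:
        tokens = [
            correct_spelling(t, model) if t.isalpha() else t for t in tokens
        ]
        # corrections may expand to the same surface form; re-tokenize once
        tokens = [t for tok in tokens for t in tokenize(tok)]
    if options.remove_stopwords:
        tokens = [t for t in tokens if t not in options.stopwords]
    if not tokens:
        return None
    return LabeledDocument(
        uid=record.uid, tokens=tuple(tokens), label=map_score_to_class(record.score)
    )


def normalize_corpus(
    records: Sequence[ReviewRecord],
    maps: NormalizationMaps | None = None,
    model: SpellingModel | None = None,
    options: NormalizeOptions | None = None,
    fit_spelling_on_corpus: bool = True,
) -> tuple[list[LabeledDocument], SkipReport]:
    """Normalize a whole corpus; the spelling model defaults to the corpus'
    own unigram counts (tokens seen at least twice), mirroring a corrector
    fitted on the training text."""
    maps = maps or load_default_maps()
    options = options or NormalizeOptions()
    if model is None and fit_spelling_on_corpus and options.correct_spelling:
        counts = Counter()
        for r in records:
            counts.update(
                t for t in tokenize(convert_chat_words(
                    convert_emoticons(r.review_text, maps), maps))
                if t.isalpha()
            )
        model = SpellingModel({w: c for w, c in counts.items() if c >= 2})
    docs: list[LabeledDocument] = []
    report = SkipReport()
    for record in records:
        doc = normalize_document(record, maps, model, options)
        if doc is None:
            report.empty_after_normalization += 1
        else:
            docs.append(doc)
    return docs, report


# --- splitting ---------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Stratified split proportions and fold count."""

    train_frac: float = 0.63
    val_frac: float = 0.07
    test_frac: float = 0.30
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.val_frac, self.test_frac)
        if not all(0 < f < 1 for f in fracs):
            raise ValueError("fractions must lie in (0, 1)")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fracs)}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test uid sets plus CV folds over train+val."""

    train: set[str]
    validation: set[str]
    test: set[str]
    folds: list[set[str]]


def _largest_remainder(n: int, fracs: Sequence[float]) -> list[int]:
    raw = [n * f for f in fracs]
    base = [int(np.floor(x)) for x in raw]
    short = n - sum(base)
    order = sorted(range(len(fracs)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def stratified_split(docs: Sequence[LabeledDocument], spec: SplitSpec) -> DatasetSplit:
    """Stratified 63/7/30 split plus stratified folds over train+validation.

    Per-class counts are allocated by largest-remainder rounding, so every
    part's class proportions deviate by at most one item from the exact
    fractions. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    by_class: dict[int, list[str]] = {}
    for d in docs:
        by_class.setdefault(d.label, []).append(d.uid)
    for label, uids in sorted(by_class.items()):
        if len(uids) < spec.n_folds:
            raise ValueError(
                f"class {label} has {len(uids)} documents, fewer than "
                f"n_folds={spec.n_folds}; cannot stratify"
            )

    train: set[str] = set()
    val: set[str] = set()
    test: set[str] = set()
    folds: list[set[str]] = [set() for _ in range(spec.n_folds)]
    for label in sorted(by_class):
        uids = sorted(by_class[label])
        rng.shuffle(uids)
        n_tr, n_va, n_te = _largest_remainder(
            len(uids), (spec.train_frac, spec.val_frac, spec.test_frac)
        )
        train.update(uids[:n_tr])
        val.update(uids[n_tr : n_tr + n_va])
        test.update(uids[n_tr + n_va :])
        dev = uids[: n_tr + n_va]
        for i, uid in enumerate(dev):
            folds[i % spec.n_folds].add(uid)
    return DatasetSplit(train=train, validation=val, test=test, folds=folds)


def top_frequent_words(
    docs: Sequence[LabeledDocument], k: int, label: int | None = None
) -> list[str]:
    """Top-``k`` tokens by descending frequency (ties lexicographic).

    With ``label`` given, only documents of that class are counted — the
    diagnostic behind the observation that the three classes share most of
    their high-frequency vocabulary.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    counts: Counter[str] = Counter()
    for d in docs:
        if label is None or d.label == label:
            counts.update(d.tokens)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [t for t, _ in ranked[:k]]


# --- normalized-corpus serialization ----------------------------------------


def write_normalized_corpus(
    docs: Sequence[LabeledDocument], path: str | Path, report: SkipReport | None = None
) -> None:
    """Write (uid, label, space-joined tokens) TSV plus a JSON skip report."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(f"{d.uid}\t{d.label}\t{' '.join(d.tokens)}\n")
    if report is not None:
        path.with_suffix(path.suffix + ".report.json").write_text(
            json.dumps(report.to_json(), indent=2), encoding="utf-8"
        )


def read_normalized_corpus(path: str | Path) -> list[LabeledDocument]:
    docs = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        uid, label, toks = line.split("\t")
        docs.append(LabeledDocument(uid=uid, tokens=tuple(toks.split()), label=int(label)))
    return docs
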