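"""Synthetic drug-review corpora with the statistical structure of the study.

Real review corpora in this domain have three properties the models must
cope with: (i) heavy class imbalance (poor/fair/good satisfaction at roughly
20.82 / 27.96 / 51.22 percent), (ii) high-frequency vocabulary shared across
all classes, with class identity carried by a minority of discriminative
sentiment tokens, and (iii) noise channels — emoticons, chat slang and
misspellings within small edit distance. The generator emulates exactly
those properties: shared-pool tokens are drawn Zipf-weighted, each class
mixes in its own disjoint discriminative pool at a configurable rate, the
1-10 score is drawn from the class's score range so the label mapping
inverts it exactly, and noise reuses the bundled normalization maps so
preprocessing has a sharp oracle.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import (
    DEFAULT_CONDITIONS,
    NormalizationMaps,
    ReviewRecord,
    load_default_maps,
)

__all__ = [
    "SyntheticConfig",
    "ClassLexicons",
    "GroundTruthDoc",
    "build_class_lexicons",
    "synthesize_corpus",
    "corpus_separability_report",
    "write_corpus_csv",
]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

# Anchor words at the head of the shared pool, mirroring the vocabulary that
# dominates all three satisfaction classes in real review corpora.
_SHARED_ANCHORS = (
    "anxiety depression medication doctor effect feel felt day week month "
    "year time sleep night side help work taking started took like better "
    "medicine life drug first good would"
).split()

_DRUGS = ("sertraline", "venlafaxine", "bupropion", "quetiapine", "alprazolam",
          "fluoxetine", "escitalopram", "lamotrigine")

_SCORE_RANGES = {0: (1, 4), 1: (5, 8), 2: (9, 10)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the study conditions being emulated."""

    n_docs: int = 1000
    class_proportions: tuple[float, float, float] = (0.2082, 0.2796, 0.5122)
    shared_vocab_size: int = 300
    class_vocab_size: int = 40
    doc_length_mean: float = 40.0
    doc_length_sd: float = 15.0
    discriminative_rate: float = 0.3
    emoticon_prob: float = 0.05
    slang_prob: float = 0.05
    misspelling_prob: float = 0.05
    zipf_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = self.class_proportions
        if any(p <= 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"class proportions must be positive and sum to 1: {props}")
        for rate in (self.discriminative_rate, self.emoticon_prob,
                     self.slang_prob, self.misspelling_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must lie in [0, 1], got {rate}")
        if self.shared_vocab_size < 1 or self.class_vocab_size < 1:
            raise ValueError("vocabulary sizes must be >= 1")


@dataclass
class ClassLexicons:
    """Shared token pool plus pairwise-disjoint per-class discriminative pools."""

    shared: list[str]
    per_class: list[list[str]]
    zipf_weights: np.ndarray

    def __post_init__(self) -> None:
        pools = [set(self.shared)] + [set(p) for p in self.per_class]
        for i in range(len(pools)):
            for j in range(i + 1, len(pools)):
                if pools[i] & pools[j]:
                    raise ValueError("lexicon pools must be pairwise disjoint")

    @property
    def all_tokens(self) -> set[str]:
        out = set(self.shared)
        for p in self.per_class:
            out |= set(p)
        return out


def _random_word(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        length = int(rng.integers(4, 10))
        word = "".join(rng.choice(list(_ALPHABET), size=length))
        if word not in taken:
            return word


def build_class_lexicons(config: SyntheticConfig) -> ClassLexicons:
    """Deterministically build the shared and per-class token pools.

    Shared-pool sampling weights follow a Zipf law with the configured
    exponent (rank-1 tokens dominate, as in real review text).
    """
    rng = np.random.default_rng(config.seed)
    taken: set[str] = set()
    shared = list(_SHARED_ANCHORS[: config.shared_vocab_size])
    taken |= set(shared)
    while len(shared) < config.shared_vocab_size:
        w = _random_word(rng, taken)
        shared.append(w)
        taken.add(w)
    per_class: list[list[str]] = []
    for _ in range(3):
        pool = []
        while len(pool) < config.class_vocab_size:
            w = _random_word(rng, taken)
            pool.append(w)
            taken.add(w)
        per_class.append(pool)
    ranks = np.arange(1, len(shared) + 1, dtype=float)
    weights = ranks**-config.zipf_exponent
    weights /= weights.sum()
    return ClassLexicons(shared=shared, per_class=per_class, zipf_weights=weights)


@dataclass
class GroundTruthDoc:
    """Clean view of one generated review, kept beside the noisy record."""

    uid: str
    label: int
    clean_tokens: list[str]
    misspelled_positions: list[int] = field(default_factory=list)
    slang_positions: list[int] = field(default_factory=list)
    emoticon_insertions: list[int] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "uid": self.uid,
            "label": self.label,
            "clean_tokens": self.clean_tokens,
            "misspelled_positions": self.misspelled_positions,
            "slang_positions": self.slang_positions,
            "emoticon_insertions": self.emoticon_insertions,
        }


def _one_edit(word: str, rng: np.random.Generator) -> str:
    """One random single-character edit (delete/transpose/replace/insert)."""
    ops = ["delete", "transpose", "replace", "insert"] if len(word) > 1 else ["replace", "insert"]
    op = ops[int(rng.integers(len(ops)))]
    i = int(rng.integers(len(word)))
    letter = _ALPHABET[int(rng.integers(26))]
    if op == "delete":
        return word[:i] + word[i + 1 :]
    if op == "transpose":
        i = min(i, len(word) - 2)
        return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
    if op == "replace":
        return word[:i] + letter + word[i + 1 :]
    return word[:i] + letter + word[i:]


def synthesize_corpus(
    config: SyntheticConfig,
    lexicons: ClassLexicons | None = None,
    maps: NormalizationMaps | None = None,
) -> tuple[list[ReviewRecord], list[GroundTruthDoc]]:
    """Generate noisy review records plus their clean ground truth.

    Each document draws its class from the configured proportions, its score
    uniformly from that class's 1-10 range (so the label mapping recovers the
    class exactly), its tokens Zipf-weighted from the shared pool with
    class-pool tokens mixed in at the discriminative rate, and then passes
    through the noise channels at the configured per-token rates.
    """
    if config.n_docs < 3:
        raise ValueError("n_docs must be at least the number of classes (3)")
    lexicons = lexicons or build_class_lexicons(config)
    maps = maps or load_default_maps()
    rng = np.random.default_rng(config.seed)
    emoticons = sorted(maps.emoticon_map)
    slang = sorted(maps.chatword_map)
    shared = np.asarray(lexicons.shared, dtype=object)

    records: list[ReviewRecord] = []
    truth: list[GroundTruthDoc] = []
    labels = rng.choice(3, size=config.n_docs, p=config.class_proportions)
    for i in range(config.n_docs):
        label = int(labels[i])
        uid = f"d{i:06d}"
        n_tokens = max(5, int(round(rng.normal(config.doc_length_mean,
                                               config.doc_length_sd))))
        disc = rng.random(n_tokens) < config.discriminative_rate
        clean = [
            (lexicons.per_class[label][int(rng.integers(config.class_vocab_size))]
             if d else str(rng.choice(shared, p=lexicons.zipf_weights)))
            for d in disc
        ]
        gt = GroundTruthDoc(uid=uid, label=label, clean_tokens=list(clean))
        emitted: list[str] = []
        for pos, tok in enumerate(clean):
            out_tok = tok
            if rng.random() < config.slang_prob:
                out_tok = slang[int(rng.integers(len(slang)))]
                gt.slang_positions.append(pos)
            elif rng.random() < config.misspelling_prob and tok.isalpha() and len(tok) >= 3:
                out_tok = _one_edit(tok, rng)
                gt.misspelled_positions.append(pos)
            emitted.append(out_tok)
            if rng.random() < config.emoticon_prob:
                emitted.append(emoticons[int(rng.integers(len(emoticons)))])
                gt.emoticon_insertions.append(pos)
        lo, hi = _SCORE_RANGES[label]
        score = int(rng.integers(lo, hi + 1))
        records.append(
            ReviewRecord(
                uid=uid,
                drug_name=_DRUGS[int(rng.integers(len(_DRUGS)))],
                condition=DEFAULT_CONDITIONS[int(rng.integers(len(DEFAULT_CONDITIONS)))],
                review_text=" ".join(emitted),
                score=score,
            )
        )
        truth.append(gt)
    return records, truth


def corpus_separability_report(
    truth: Sequence[GroundTruthDoc], lexicons: ClassLexicons
) -> dict:
    """Summary statistics tests can assert generated difficulty against.

    Reports the measured per-class discriminative-token rate (over clean
    tokens) and the most-frequent-class baseline accuracy; a corpus whose
    discriminative rate is zero is flagged unseparable.
    """
    class_pools = [set(p) for p in lexicons.per_class]
    rates = []
    class_counts = np.zeros(3)
    for label in range(3):
        docs = [t for t in truth if t.label == label]
        class_counts[label] = len(docs)
        n_tok = sum(len(t.clean_tokens) for t in docs)
        n_disc = sum(
            sum(tok in class_pools[label] for tok in t.clean_tokens) for t in docs
        )
        rates.append(n_disc / n_tok if n_tok else 0.0)
    baseline = float(class_counts.max() / class_counts.sum()) if class_counts.sum() else 0.0
    overall = float(np.mean([r for r, c in zip(rates, class_counts) if c > 0]))
    return {
        "per_class_discriminative_rate": rates,
        "overall_discriminative_rate": overall,
        "majority_class_baseline_accuracy": baseline,
        "class_counts": class_counts.astype(int).tolist(),
        "unseparable": overall == 0.0,
    }


def write_corpus_csv(
    records: Sequence[ReviewRecord],
    path: str | Path,
    truth: Sequence[GroundTruthDoc] | None = None,
) -> None:
    """Emit the same delimiter-separated schema the reader consumes, plus a
    ground-truth sidecar JSON when available."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["uniqueID", "drugName", "condition", "review", "score"])
        for r in records:
            writer.writerow([r.uid, r.drug_name, r.condition, r.review_text, r.score])
    if truth is not None:
        path.with_suffix(path.suffix + ".truth.json").write_text(
            json.dumps([t.to_json() for t in truth]), encoding="utf-8"
        )
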