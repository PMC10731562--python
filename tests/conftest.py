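import numpy as np
import pytest

from uimf.preprocess import (
    LabeledDocument,
    NormalizeOptions,
    load_default_maps,
    normalize_corpus,
)
from uimf.synthetic import SyntheticConfig, build_class_lexicons, synthesize_corpus


@pytest.fixture(scope="session")
def maps():
    return load_default_maps()


@pytest.fixture(scope="session")
def small_corpus():
    """300 normalized synthetic documents with mild noise (shared by tests)."""
    cfg = SyntheticConfig(
        n_docs=300, seed=11, doc_length_mean=20, doc_length_sd=5,
        shared_vocab_size=150, class_vocab_size=25,
    )
    records, truth = synthesize_corpus(cfg)
    docs, _ = normalize_corpus(records)
    return docs


@pytest.fixture(scope="session")
def noisy_records():
    """50 records with heavy emoticon/slang noise for idempotence checks."""
    cfg = SyntheticConfig(
        n_docs=50, seed=7, doc_length_mean=15, doc_length_sd=4,
        emoticon_prob=0.3, slang_prob=0.3, misspelling_prob=0.1,
    )
    records, _ = synthesize_corpus(cfg)
    return records


@pytest.fixture
def table1_csv(tmp_path):
    """A review file shaped like the open drug-review corpora."""
    rows = [
        ("206461", "Valsartan", "Left ventricular dysfunction",
         "It has no side effect, I take it in combination of Bystolic 5 Mg and Fish Oil", "9"),
        ("92703", "Keppera", "Epilepsy",
         "I Ve had nothing but problems with the Keppera: constant shaking in my arms", "1"),
        ("121333", "Venlafaxine", "Depression",
         "My go started me on venlafaxine yesterday to help with depression", "4"),
    ]
    path = tmp_path / "reviews.csv"
    with path.open("w", encoding="utf-8") as fh:
        fh.write("uniqueID,drugName,condition,review,score\n")
        for r in rows:
            fh.write(",".join(f'"{c}"' if "," in c else c for c in r) + "\n")
    return path


def damerau_distance(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein distance (edits include transposition)."""
    d = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(len(a) + 1):
        d[i][0] = i
    for j in range(len(b) + 1):
        d[0][j] = j
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            cost = a[i - 1] != b[j - 1]
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1, d[i - 1][j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[-1][-1]


def make_docs(per_class: int, seed: int = 0, n_tokens: int = 8):
    """Tiny hand-steerable labeled corpus: class token mixed with shared ones."""
    rng = np.random.default_rng(seed)
    shared = ["day", "feel", "took", "week", "doctor"]
    class_tokens = {0: "awful", 1: "okay", 2: "great"}
    docs = []
    for label in (0, 1, 2):
        for i in range(per_class):
            toks = [class_tokens[label]] + list(rng.choice(shared, size=n_tokens - 1))
            docs.append(LabeledDocument(uid=f"c{label}_{i}", tokens=tuple(toks), label=label))
    return docs
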