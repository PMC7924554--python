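"""Shared fixtures and independent brute-force oracles.

The oracles here never touch the index machinery: suffix arrays are
naive sorts of explicit suffixes, and every query is answered by a
direct scan of the plain (T, A) pair.
"""

from __future__ import annotations

import random

import pytest

from labelidx import EPSILON, LabeledText, LabelHierarchy, TextBuffer

# ---------------------------------------------------------------------------
# The three-sequence example used throughout: T = AACAGC$ATCAAC$AGCTTT$
# with labels L1.2^3 L2^3 ε L3^3 L1.1^3 ε L2^3 ε^4.
# ---------------------------------------------------------------------------

EXAMPLE_SEQS = [("s1", "AACAGC"), ("s2", "ATCAAC"), ("s3", "AGCTTT")]
EXAMPLE_LABELS = (["L1.2"] * 3 + ["L2"] * 3 + [EPSILON]
                  + ["L3"] * 3 + ["L1.1"] * 3 + [EPSILON]
                  + ["L2"] * 3 + [EPSILON] * 4)
EXAMPLE_TEXT = "AACAGC$ATCAAC$AGCTTT$"
EXAMPLE_HIERARCHY = {"L1": ["L1.1", "L1.2"], "L2": None, "L3": None}


@pytest.fixture
def example_lt() -> LabeledText:
    return LabeledText(TextBuffer(EXAMPLE_SEQS), list(EXAMPLE_LABELS))


@pytest.fixture
def example_hierarchy() -> LabelHierarchy:
    return LabelHierarchy.from_obj(EXAMPLE_HIERARCHY)


# ---------------------------------------------------------------------------
# Naive oracles
# ---------------------------------------------------------------------------

def naive_suffix_array(seqs: list[tuple[str, str]]) -> list[int]:
    """Sort all suffixes explicitly: terminator k sorts as (0, k); letters
    sort after every terminator."""
    text = "".join(s + "$" for _, s in seqs)
    key = []
    sent = 0
    for c in text:
        if c == "$":
            key.append((0, sent))
            sent += 1
        else:
            key.append((1, ord(c)))
    return sorted(range(len(text)), key=lambda i: key[i:])


def naive_bwt(seqs: list[tuple[str, str]]) -> str:
    text = "".join(s + "$" for _, s in seqs)
    sa = naive_suffix_array(seqs)
    return "".join(text[(i - 1) % len(text)] for i in sa)


def naive_occurrences(text: str, pattern: str) -> list[int]:
    if not pattern:
        return list(range(len(text)))
    return [i for i in range(len(text) - len(pattern) + 1)
            if text[i:i + len(pattern)] == pattern]


class NaiveLabeledOracle:
    """Answers every query by scanning (T, A)."""

    def __init__(self, lt: LabeledText):
        self.text = lt.text.characters
        self.labels = list(lt.labels)

    def label_at(self, t):
        return self.labels[t]

    def find_pattern(self, p):
        return naive_occurrences(self.text, p)

    def find_label(self, lab):
        return [i for i, a in enumerate(self.labels) if a == lab]

    def find_pattern_label(self, p, lab):
        return [i for i in self.find_pattern(p) if self.labels[i] == lab]

    def count_pattern_label(self, p, lab):
        return len(self.find_pattern_label(p, lab))

    def find_pattern_label_at(self, p, lab, k):
        occs = self.find_pattern(p)
        if k is None:  # ANY
            m = len(p)
            return [i for i in occs
                    if any(self.labels[i + q] == lab for q in range(m))]
        return [i for i in occs if self.labels[i + k] == lab]

    def find_family(self, members):
        members = set(members)
        return [i for i, a in enumerate(self.labels) if a in members]


def random_labeled_text(rng: random.Random, max_n: int = 2000,
                        max_labels: int = 20,
                        alphabet: str = "ACGT") -> LabeledText:
    """An arbitrary labeled text built directly, independent of the
    package's synthetic generators."""
    nseq = rng.randint(1, 4)
    nlabels = rng.randint(1, max_labels)
    names = [f"X{i}" for i in range(nlabels)]
    per_seq = max(2, max_n // nseq)
    seqs, labels = [], []
    for k in range(nseq):
        length = rng.randint(2, per_seq)
        seqs.append((f"r{k}", "".join(rng.choice(alphabet)
                                      for _ in range(length))))
        pos = 0
        labs = [EPSILON] * length
        while pos < length:
            run = rng.randint(1, 8)
            lab = rng.choice(names + [EPSILON, EPSILON])
            for p in range(pos, min(pos + run, length)):
                labs[p] = lab
            pos += run
        labels.extend(labs + [EPSILON])
    return LabeledText(TextBuffer(seqs), labels)


def random_patterns(rng: random.Random, text: str, count: int) -> list[str]:
    """Mix of substrings actually present and arbitrary (possibly absent)
    strings."""
    out = []
    clean = text.replace("$", "")
    for _ in range(count):
        if rng.random() < 0.7 and len(clean) > 2:
            i = rng.randrange(0, len(clean) - 1)
            out.append(clean[i:i + rng.randint(1, 5)])
        else:
            out.append("".join(rng.choice("ACGT")
                               for _ in range(rng.randint(1, 4))))
    return [p for p in out if p]
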