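"""Multi-string suffix array, Burrows-Wheeler transform and backward search.

A collection of sequences is concatenated with one terminator ``$`` per
sequence.  Suffixes are ordered with the terminator of sequence *k*
sorting before the terminator of sequence *k+1*, and every terminator
sorting before every alphabet letter; internally each terminator is a
distinct integer symbol, which keeps the LF mapping a true permutation,
while the exposed BWT string writes them all uniformly as ``$``.

The suffix array is built by prefix doubling (numpy lexsort); the text is
recovered by LF-iteration and located through a sampled suffix array.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

SENTINEL = "$"

__all__ = ["TextBuffer", "FMIndex", "build_suffix_array", "SENTINEL"]


class TextBuffer:
    """Concatenation of ``$``-terminated sequences.

    Parameters
    ----------
    sequences:
        Iterable of (record_id, sequence) pairs; sequences must not
        contain the terminator themselves.
    """

    def __init__(self, sequences: Iterable[tuple[str, str]]):
        ids, starts, parts = [], [], []
        pos = 0
        for rid, seq in sequences:
            if SENTINEL in seq:
                raise ValueError(f"record {rid!r} contains the terminator {SENTINEL!r}")
            if not seq:
                raise ValueError(f"record {rid!r} is empty")
            ids.append(rid)
            starts.append(pos)
            parts.append(seq + SENTINEL)
            pos += len(seq) + 1
        if not parts:
            raise ValueError("no sequences supplied")
        self.record_ids: list[str] = ids
        self.sequence_boundaries: list[int] = starts
        self.characters: str = "".join(parts)
        self.n: int = pos
        self.alphabet: list[str] = sorted(set(self.characters) - {SENTINEL})
        self.sigma: int = len(self.alphabet) + 1

    @property
    def num_sequences(self) -> int:
        return len(self.record_ids)

    def to_ints(self) -> np.ndarray:
        """Integer form: terminator of sequence k -> k; letters follow."""
        nsent = self.num_sequences
        letter_code = {c: nsent + i for i, c in enumerate(self.alphabet)}
        out = np.empty(self.n, dtype=np.int64)
        sent = 0
        for i, c in enumerate(self.characters):
            if c == SENTINEL:
                out[i] = sent
                sent += 1
            else:
                out[i] = letter_code[c]
        return out

    def record_of(self, t: int) -> tuple[str, int]:
        """Map a global text position to (record_id, offset-in-record)."""
        if not 0 <= t < self.n:
            raise IndexError(f"text position {t} out of range")
        k = int(np.searchsorted(np.asarray(self.sequence_boundaries), t, side="right")) - 1
        return self.record_ids[k], t - self.sequence_boundaries[k]


def build_suffix_array(text: TextBuffer | Sequence[int]) -> np.ndarray:
    """Suffix array by prefix doubling.

    Accepts a :class:`TextBuffer` (converted to distinct-terminator
    integers) or an integer sequence directly.
    """
    ints = text.to_ints() if isinstance(text, TextBuffer) else np.asarray(text, np.int64)
    n = ints.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    _, rank = np.unique(ints, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        diff = np.empty(n, dtype=np.int64)
        diff[0] = 0
        diff[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        newrank = np.empty(n, dtype=np.int64)
        newrank[order] = np.cumsum(diff)
        rank = newrank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


class FMIndex:
    """BWT with C table, Occ counts and a sampled suffix array.

    ``sample_rate`` controls locate cost: suffix-array values are kept for
    every text position divisible by the rate, plus every terminator
    position, so LF-stepping reaches a sample within ``sample_rate``
    steps.
    """

    def __init__(self, text: TextBuffer, sa: np.ndarray | None = None,
                 sample_rate: int = 32):
        if sample_rate < 1:
            raise ValueError("sample_rate must be >= 1")
        self.text_meta = _TextMeta.from_buffer(text)
        ints = text.to_ints()
        if sa is None:
            sa = build_suffix_array(ints)
        sa = np.asarray(sa, dtype=np.int64)
        n = ints.size
        self.n = n
        self.sample_rate = sample_rate
        self.bwt_ints = ints[(sa - 1) % n]
        self._finish_support()
        # Samples: text position -> row and row -> text position.
        sampled = (sa % sample_rate == 0)
        term_rows = np.flatnonzero(ints[sa] < self.nsent)
        sampled[term_rows] = True
        rows = np.flatnonzero(sampled)
        self.sa_samples: dict[int, int] = {int(r): int(sa[r]) for r in rows}
        self._pos_to_row: dict[int, int] = {v: k for k, v in self.sa_samples.items()}

    # -- construction helpers ---------------------------------------------

    def _finish_support(self) -> None:
        meta = self.text_meta
        self.nsent = meta.num_sequences
        nsym = self.nsent + len(meta.alphabet)
        counts = np.bincount(self.bwt_ints, minlength=nsym)
        self.C = np.concatenate([[0], np.cumsum(counts)])[:-1]
        # Dense Occ for letters (terminators occur once each; their single
        # position suffices).
        self._occ = {c: np.cumsum(self.bwt_ints == c, dtype=np.int64)
                     for c in range(self.nsent, nsym)}
        self._term_row = {int(c): int(np.flatnonzero(self.bwt_ints == c)[0])
                          for c in range(self.nsent)}
        self._letter_code = {ch: self.nsent + i for i, ch in enumerate(meta.alphabet)}

    @classmethod
    def from_parts(cls, meta: "_TextMeta", bwt_ints: np.ndarray,
                   sa_samples: dict[int, int], sample_rate: int) -> "FMIndex":
        """Reassemble from serialized components (no suffix array needed)."""
        obj = cls.__new__(cls)
        obj.text_meta = meta
        obj.n = int(bwt_ints.size)
        obj.sample_rate = sample_rate
        obj.bwt_ints = np.asarray(bwt_ints, dtype=np.int64)
        obj._finish_support()
        obj.sa_samples = {int(k): int(v) for k, v in sa_samples.items()}
        obj._pos_to_row = {v: k for k, v in obj.sa_samples.items()}
        return obj

    # -- views -------------------------------------------------------------

    @property
    def bwt(self) -> str:
        """The BWT as a string, all terminators written as ``$``."""
        letters = [SENTINEL] * self.nsent + list(self.text_meta.alphabet)
        return "".join(letters[c] for c in self.bwt_ints)

    def occ(self, symbol: int, i: int) -> int:
        """Occurrences of integer symbol in bwt[0..i] (i may be -1)."""
        if i < 0:
            return 0
        if symbol < self.nsent:
            return int(self._term_row[symbol] <= i)
        return int(self._occ[symbol][i])

    # -- core operations ----------------------------------------------------

    def lf(self, i: int) -> int:
        """LF mapping: row of text position SA[i]-1 (mod n)."""
        c = int(self.bwt_ints[i])
        if c < self.nsent:
            return c  # terminator rows occupy the first nsent rows in order
        return int(self.C[c]) + self.occ(c, i) - 1

    def backward_search(self, pattern: str) -> tuple[int, int]:
        """Row interval [i, j] of suffixes prefixed by ``pattern``.

        Empty pattern gives the full interval; an empty result is
        returned as (0, -1)-style (i > j).
        """
        i, j = 0, self.n - 1
        for ch in reversed(pattern):
            c = self._letter_code.get(ch)
            if c is None:
                return 0, -1
            i = int(self.C[c]) + self.occ(c, i - 1)
            j = int(self.C[c]) + self.occ(c, j) - 1
            if i > j:
                return 0, -1
        return i, j

    def sa_value(self, row: int) -> int:
        """SA[row], by LF-stepping to the nearest sampled row."""
        steps = 0
        r = row
        while r not in self.sa_samples:
            r = self.lf(r)
            steps += 1
        return (self.sa_samples[r] + steps) % self.n

    def locate(self, interval: tuple[int, int]) -> list[int]:
        """Text positions of every row in [i, j] (interval order)."""
        i, j = interval
        return [self.sa_value(r) for r in range(i, j + 1)]

    def row_of_text_position(self, t: int) -> int:
        """The row whose BWT character is the text character at ``t``.

        That is, the row r with SA[r] = (t+1) mod n.
        """
        if not 0 <= t < self.n:
            raise IndexError(f"text position {t} out of range")
        target = (t + 1) % self.n
        p = target
        while p not in self._pos_to_row:
            p += 1  # every sample_rate-th position is sampled, so bounded
        r = self._pos_to_row[p]
        for _ in range(p - target):
            r = self.lf(r)
        return r

    def invert(self) -> str:
        """Reconstruct the original concatenated text from the BWT."""
        seqs = []
        for k in range(self.nsent):
            # Row k starts with terminator k; its BWT character is the last
            # letter of sequence k.  LF-iterate until the previous
            # terminator closes the sequence.
            chars = []
            r = k
            while True:
                c = int(self.bwt_ints[r])
                if c < self.nsent:
                    break
                chars.append(self.text_meta.alphabet[c - self.nsent])
                r = self.lf(r)
            seqs.append("".join(reversed(chars)) + SENTINEL)
        return "".join(seqs)


class _TextMeta:
    """The part of a TextBuffer an index must retain: ids, boundaries,
    alphabet.  (The characters themselves live only in the BWT.)"""

    __slots__ = ("record_ids", "sequence_boundaries", "alphabet", "n")

    def __init__(self, record_ids, sequence_boundaries, alphabet, n):
        self.record_ids = list(record_ids)
        self.sequence_boundaries = list(sequence_boundaries)
        self.alphabet = list(alphabet)
        self.n = int(n)

    @classmethod
    def from_buffer(cls, text: TextBuffer) -> "_TextMeta":
        return cls(text.record_ids, text.sequence_boundaries, text.alphabet, text.n)

    @property
    def num_sequences(self) -> int:
        return len(self.record_ids)

    def record_of(self, t: int) -> tuple[str, int]:
        k = int(np.searchsorted(np.asarray(self.sequence_boundaries), t,
                                side="right")) - 1
        return self.record_ids[k], t - self.sequence_boundaries[k]
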