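"""Labeled-text indexes: TL, TL_BW and the HT baseline.

A labeled text is a pair (T, A): the concatenated ``$``-terminated
sequences plus exactly one label per position, the empty label ε
(represented as ``""``) marking unlabeled positions and every terminator.
Because consecutive positions usually share a label, only the *changing*
labels are kept: a boundary bit vector marks run starts and the run
labels form the compressed label sequence, stored in a wavelet tree.

* The **TL-index** stores the runs in text order (B_A, W_A over A').
* The **TL_BW-index** stores them in BWT order (B_D, W_D over D'), where
  D[r] is the label of the BWT character at row r, i.e. of text position
  SA[r]-1; this lets combined pattern+label queries run as a range query
  inside the wavelet tree instead of locating every pattern occurrence.
* The **HT-index** is the baseline: a map label -> (start, end) spans
  plus the boundary vector and the run labels stored in plain form.

All three answer the same five queries (label-at-position, pattern
search, label search, combined count/find, and the offset variants) and
must agree with each other and with a direct scan of (T, A).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .fmindex import FMIndex, TextBuffer, build_suffix_array
from .succinct import BitVector, ShapeNode, WaveletTree, balanced_shape, huffman_shape

EPSILON = ""  # the empty label placed on unlabeled positions and terminators


class _Any:
    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ANY"


ANY = _Any()  # offset wildcard: label may sit at any position of the pattern

__all__ = [
    "EPSILON", "ANY", "LabeledText", "CompressedLabelSequence",
    "LabelHierarchy", "hierarchy_to_shape", "compress_labels",
    "labels_in_bwt_order", "TLIndex", "TLBWIndex", "HTIndex",
    "build_tl", "build_tlbw", "build_ht", "empirical_entropy", "text_entropy",
]


# ---------------------------------------------------------------------------
# Labeled text
# ---------------------------------------------------------------------------

class LabeledText:
    """The pair (T, A): a multi-sequence text and one label per position."""

    def __init__(self, text: TextBuffer, labels: Sequence[str]):
        labels = list(labels)
        if len(labels) != text.n:
            raise ValueError(
                f"label string length {len(labels)} != text length {text.n}")
        for k, start in enumerate(text.sequence_boundaries):
            end = (text.sequence_boundaries[k + 1]
                   if k + 1 < text.num_sequences else text.n)
            if labels[end - 1] != EPSILON:
                raise ValueError(
                    f"terminator of record {text.record_ids[k]!r} must carry ε")
        self.text = text
        self.labels = labels

    @property
    def n(self) -> int:
        return self.text.n

    @property
    def label_set(self) -> list[str]:
        """The distinct non-ε labels, sorted."""
        return sorted(set(self.labels) - {EPSILON})


# ---------------------------------------------------------------------------
# Run compression of a label string
# ---------------------------------------------------------------------------

@dataclass
class CompressedLabelSequence:
    """Run-boundary bits plus the label at each run start."""

    boundary: BitVector
    runs: list[str]

    @property
    def length(self) -> int:
        return len(self.runs)

    def run_interval(self, k: int) -> tuple[int, int]:
        """Inclusive [start, end] positions covered by run k."""
        n = len(self.boundary)
        start = self.boundary.select(1, k + 1)
        end = self.boundary.select(1, k + 2) - 1 if k + 1 < self.length else n - 1
        return start, end

    def run_of(self, i: int) -> int:
        """Index of the run containing position i."""
        return self.boundary.rank(1, i) - 1

    def expand(self) -> list[str]:
        """Reconstruct the full label string."""
        out = []
        for k, lab in enumerate(self.runs):
            s, e = self.run_interval(k)
            out.extend([lab] * (e - s + 1))
        return out


def compress_labels(labels: Sequence[str]) -> CompressedLabelSequence:
    """Boundary bit vector (1 where the label changes) and run labels."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label string")
    bits = [1] + [0 if labels[i] == labels[i - 1] else 1
                  for i in range(1, len(labels))]
    runs = [labels[i] for i, b in enumerate(bits) if b]
    return CompressedLabelSequence(BitVector(bits), runs)


def labels_in_bwt_order(lt: LabeledText, sa: np.ndarray) -> list[str]:
    """D: label of the BWT character at each row, D[r] = A[(SA[r]-1) mod n]."""
    labels = lt.labels
    n = lt.n
    return [labels[(int(p) - 1) % n] for p in sa]


# ---------------------------------------------------------------------------
# Label hierarchies and wavelet-tree shaping
# ---------------------------------------------------------------------------

class LabelHierarchy:
    """Named families of labels (possibly nested).

    ``items`` is an ordered list whose entries are either plain labels or
    ``(family_name, sub_items)`` pairs.  Every label must be reachable by
    exactly one path.
    """

    def __init__(self, items: list):
        self.items = items
        seen: set[str] = set()
        for lab in self.labels():
            if lab in seen:
                raise ValueError(f"label {lab!r} appears in two families")
            seen.add(lab)

    @classmethod
    def from_obj(cls, obj) -> "LabelHierarchy":
        """Build from a YAML/JSON-style object.

        A mapping ``{family: members}`` (members may be None for a bare
        label), a list of labels/mappings, or a mix of both.
        """
        return cls(cls._items(obj))

    @staticmethod
    def _items(obj) -> list:
        items: list = []
        if isinstance(obj, dict):
            entries = obj.items()
        elif isinstance(obj, list):
            entries = []
            for e in obj:
                if isinstance(e, dict):
                    entries.extend(e.items())
                else:
                    entries.append((e, None))
        else:
            raise TypeError(f"cannot interpret hierarchy object {obj!r}")
        for name, members in entries:
            if members is None:
                items.append(str(name))
            else:
                items.append((str(name), LabelHierarchy._items(members)))
        return items

    def to_obj(self):
        def conv(items):
            out = []
            for it in items:
                if isinstance(it, tuple):
                    out.append({it[0]: conv(it[1])})
                else:
                    out.append(it)
            return out
        return conv(self.items)

    def labels(self) -> list[str]:
        out: list[str] = []

        def walk(items):
            for it in items:
                if isinstance(it, tuple):
                    walk(it[1])
                else:
                    out.append(it)
        walk(self.items)
        return out

    def families(self) -> dict[str, list[str]]:
        """Mapping family name -> all member labels (transitively)."""
        fams: dict[str, list[str]] = {}

        def walk(items) -> list[str]:
            leaves: list[str] = []
            for it in items:
                if isinstance(it, tuple):
                    sub = walk(it[1])
                    if it[0] in fams:
                        raise ValueError(f"family {it[0]!r} defined twice")
                    fams[it[0]] = sub
                    leaves.extend(sub)
                else:
                    leaves.append(it)
            return leaves
        walk(self.items)
        return fams


def hierarchy_to_shape(hierarchy: LabelHierarchy,
                       extra_labels: Iterable[str] = ()) -> ShapeNode:
    """Binary topology mirroring an n-ary hierarchy.

    Each family becomes a binary subtree whose leaf set is exactly the
    family's labels, with the subtree root carrying the family name so
    family queries can enter there.  ε (and any ``extra_labels`` not in
    the hierarchy) are appended at the top level.
    """

    def build_items(items) -> ShapeNode:
        nodes = [build_item(it) for it in items]
        return binarize(nodes)

    def build_item(it) -> ShapeNode:
        if isinstance(it, tuple):
            name, sub = it
            # a singleton family collapses onto its member's leaf, which
            # then carries the family name as an alias
            node = build_items(sub)
            node.label = name
            return node
        return ShapeNode(symbol=it)

    def binarize(nodes: list[ShapeNode]) -> ShapeNode:
        if not nodes:
            raise ValueError("empty hierarchy level")
        while len(nodes) > 1:
            merged = []
            for a, b in zip(nodes[::2], nodes[1::2]):
                merged.append(ShapeNode(left=a, right=b))
            if len(nodes) % 2:
                merged.append(nodes[-1])
            nodes = merged
        return nodes[0]

    top = [build_item(it) for it in hierarchy.items]
    declared = set(hierarchy.labels())
    for lab in sorted(set(extra_labels) - declared, key=str):
        top.append(ShapeNode(symbol=lab))
    if EPSILON not in declared and not any(
            n.is_leaf and n.symbol == EPSILON for n in top):
        top.append(ShapeNode(symbol=EPSILON))
    return binarize(top)


def _choose_shape(runs: list[str], mode: str,
                  hierarchy: LabelHierarchy | None) -> ShapeNode:
    if mode == "auto":
        mode = "hierarchy" if hierarchy is not None else "huffman"
    if mode == "hierarchy":
        if hierarchy is None:
            raise ValueError("hierarchy shape requested without a hierarchy")
        return hierarchy_to_shape(hierarchy, extra_labels=set(runs))
    if mode == "huffman":
        freqs = Counter(runs)
        if len(freqs) == 1:
            return ShapeNode(symbol=next(iter(freqs)))
        return huffman_shape(dict(freqs))
    if mode == "balanced":
        return balanced_shape(runs)
    raise ValueError(f"unknown shape mode {mode!r}")


# ---------------------------------------------------------------------------
# Entropy helpers (size reporting)
# ---------------------------------------------------------------------------

def empirical_entropy(seq: Sequence) -> float:
    """Zeroth-order empirical entropy H0 in bits per symbol."""
    seq = list(seq)
    if not seq:
        return 0.0
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in Counter(seq).values())


def text_entropy(text: str, k: int = 2) -> float:
    """Order-k empirical entropy H_k of a string, bits per symbol."""
    n = len(text)
    if n == 0 or k < 0:
        return 0.0
    if k == 0:
        return empirical_entropy(text)
    contexts: dict[str, Counter] = {}
    for i in range(k, n):
        contexts.setdefault(text[i - k:i], Counter())[text[i]] += 1
    total = 0.0
    for counts in contexts.values():
        m = sum(counts.values())
        total += m * (-sum((c / m) * math.log2(c / m) for c in counts.values()))
    return total / n


# ---------------------------------------------------------------------------
# Index classes
# ---------------------------------------------------------------------------

@dataclass
class IndexStats:
    """Deterministic size/entropy report for a built index."""

    n: int
    sigma: int
    l: int
    a: int
    d: int
    a_over_n: float
    d_over_n: float
    h0_runs: float
    h0_boundary: float
    hk_text: float
    k: int
    component_bits: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {f: getattr(self, f) for f in
               ("n", "sigma", "l", "a", "d", "a_over_n", "d_over_n",
                "h0_runs", "h0_boundary", "hk_text", "k")}
        out["component_bits"] = dict(self.component_bits)
        return out


class _BaseIndex:
    """Shared query surface for the three index kinds."""

    kind: str = "?"

    def __init__(self, fm: FMIndex, hierarchy: LabelHierarchy | None,
                 stats: IndexStats):
        self.fm = fm
        self.hierarchy = hierarchy
        self._stats = stats

    # -- generic queries ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.fm.n

    def label_at(self, t: int) -> str:
        raise NotImplementedError

    def find_pattern(self, pattern: str) -> list[int]:
        """Text positions of every occurrence of ``pattern``, sorted."""
        i, j = self.fm.backward_search(pattern)
        if i > j:
            return []
        return sorted(self.fm.locate((i, j)))

    def find_label(self, label: str) -> list[int]:
        raise NotImplementedError

    def find_family(self, family: str) -> list[int]:
        raise NotImplementedError

    def count_pattern_label(self, pattern: str, label: str) -> int:
        """Positions labeled ``label`` that begin an occurrence of ``pattern``."""
        return len(self.find_pattern_label(pattern, label))

    def find_pattern_label(self, pattern: str, label: str) -> list[int]:
        if not pattern:
            raise ValueError("pattern must be non-empty")
        i, j = self.fm.backward_search(pattern)
        if i > j:
            return []
        return sorted(p for p in self.fm.locate((i, j))
                      if self.label_at(p) == label)

    def find_pattern_label_at(self, pattern: str, label: str,
                              offset: "int | _Any") -> list[int]:
        """Occurrences of ``pattern`` with ``label`` at a pattern offset.

        ``offset`` is 0-based within the pattern; ``ANY`` asks for the
        label anywhere inside the occurrence window.
        """
        if not pattern:
            raise ValueError("pattern must be non-empty")
        if offset is not ANY and not 0 <= offset < len(pattern):
            raise ValueError(f"offset {offset} outside pattern of length {len(pattern)}")
        occs = self.find_pattern(pattern)
        if offset is ANY:
            m = len(pattern)
            return sorted(p for p in occs
                          if self._label_in_window(p, p + m - 1, label))
        return sorted(p for p in occs if self.label_at(p + offset) == label)

    def _label_in_window(self, lo: int, hi: int, label: str) -> bool:
        return any(self.label_at(q) == label for q in range(lo, hi + 1))

    def stats(self) -> dict:
        return self._stats.as_dict()

    def _family_members(self, family: str) -> list[str]:
        if self.hierarchy is None:
            raise KeyError(f"no hierarchy attached; unknown family {family!r}")
        fams = self.hierarchy.families()
        if family not in fams:
            raise KeyError(f"family {family!r} not in hierarchy")
        return fams[family]


class _WTIndex(_BaseIndex):
    """Common machinery for TL and TL_BW: boundary bits + wavelet tree."""

    def __init__(self, fm, cls: CompressedLabelSequence, wt: WaveletTree,
                 hierarchy, stats):
        super().__init__(fm, hierarchy, stats)
        self.cls = cls
        self.W = wt

    def _expand_runs(self, run_indices: Iterable[int]) -> list[int]:
        out: list[int] = []
        for k in run_indices:
            s, e = self.cls.run_interval(k)
            out.extend(range(s, e + 1))
        return out


class TLIndex(_WTIndex):
    """Text-order index: FM-index + B_A + W_A over A'."""

    kind = "tl"

    def label_at(self, t: int) -> str:
        if not 0 <= t < self.n:
            raise IndexError(f"text position {t} out of range")
        return self.W.access(self.cls.run_of(t))

    def find_label(self, label: str) -> list[int]:
        return sorted(self._expand_runs(self.W.positions_of(label)))

    def find_family(self, family: str) -> list[int]:
        # One entry into the wavelet tree at the family's node; no
        # per-member iteration.
        return sorted(self._expand_runs(self.W.positions_under(family)))

    def _label_in_window(self, lo: int, hi: int, label: str) -> bool:
        # Only two boundary lookups: the labels inside [lo, hi] are
        # exactly the runs run_of(lo)..run_of(hi).
        r1 = self.cls.run_of(lo)
        r2 = self.cls.run_of(hi)
        return bool(self.W.range_locate(label, r1, r2))


class TLBWIndex(_WTIndex):
    """BWT-order index: FM-index + B_D + W_D over D'."""

    kind = "tlbw"

    def __init__(self, *args, **kw):
        super().__init__(*args, **kw)
        self.last_pl_stats: dict = {}

    def label_at(self, t: int) -> str:
        if not 0 <= t < self.n:
            raise IndexError(f"text position {t} out of range")
        row = self.fm.row_of_text_position(t)
        return self.W.access(self.cls.run_of(row))

    def _rows_to_text(self, rows: Iterable[int]) -> list[int]:
        n = self.n
        return [(self.fm.sa_value(r) - 1) % n for r in rows]

    def find_label(self, label: str) -> list[int]:
        rows = self._expand_runs(self.W.positions_of(label))
        return sorted(self._rows_to_text(rows))

    def find_family(self, family: str) -> list[int]:
        rows = self._expand_runs(self.W.positions_under(family))
        return sorted(self._rows_to_text(rows))

    # -- combined pattern+label queries ------------------------------------

    def _pattern_label_rows(self, pattern: str, label: str) -> list[int]:
        """BWT rows r with BWT character = pattern[0], suffix(r) prefixed
        by pattern[1:], and D[r] = label — i.e. the rows whose BWT
        character is the first letter of an occurrence carrying the label.

        D[r] labels the BWT character (text position SA[r]-1), so the
        range query must run over the interval of pattern[1:]; the runs it
        returns are clamped to that interval and filtered on the BWT
        character.  The LF step maps the surviving rows one-to-one onto
        the backward-search interval of the full pattern.
        """
        if not pattern:
            raise ValueError("pattern must be non-empty")
        fm = self.fm
        n = fm.n
        if len(pattern) == 1:
            i1, j1 = 0, n - 1
        else:
            i1, j1 = fm.backward_search(pattern[1:])
        c0 = fm._letter_code.get(pattern[0])
        if c0 is None or i1 > j1:
            self.last_pl_stats = {"z": 0, "y": 0, "occ": 0}
            return []
        ri = self.cls.run_of(i1)
        rj = self.cls.run_of(j1)
        Z = self.W.range_locate(label, ri, rj)
        rows: list[int] = []
        contributing = 0
        for z in Z:
            s, e = self.cls.run_interval(z)
            lo, hi = max(s, i1), min(e, j1)  # clamp run to the interval
            if lo > hi:
                continue
            hits = np.flatnonzero(fm.bwt_ints[lo:hi + 1] == c0)
            if hits.size:
                contributing += 1
                rows.extend(int(h) + lo for h in hits)
        pi, pj = fm.backward_search(pattern)
        occ = max(0, pj - pi + 1)
        self.last_pl_stats = {"z": contributing, "y": len(rows), "occ": occ}
        assert contributing <= len(rows) <= occ
        return rows

    def count_pattern_label(self, pattern: str, label: str) -> int:
        return len(self._pattern_label_rows(pattern, label))

    def find_pattern_label(self, pattern: str, label: str) -> list[int]:
        rows = self._pattern_label_rows(pattern, label)
        return sorted(self._rows_to_text(rows))


class HTIndex(_BaseIndex):
    """Baseline: FM-index + plain run labels + label -> spans map."""

    kind = "ht"

    def __init__(self, fm, cls: CompressedLabelSequence,
                 label_spans: dict[str, list[tuple[int, int]]],
                 hierarchy, stats):
        super().__init__(fm, hierarchy, stats)
        self.cls = cls
        self.label_spans = label_spans

    def label_at(self, t: int) -> str:
        if not 0 <= t < self.n:
            raise IndexError(f"text position {t} out of range")
        return self.cls.runs[self.cls.run_of(t)]

    def find_label(self, label: str) -> list[int]:
        if label == EPSILON:
            # ε spans are not in the map; read them off the plain runs.
            out = []
            for k, r in enumerate(self.cls.runs):
                if r == EPSILON:
                    s, e = self.cls.run_interval(k)
                    out.extend(range(s, e + 1))
            return out
        out = []
        for s, e in self.label_spans.get(label, []):
            out.extend(range(s, e + 1))
        return sorted(out)

    def find_family(self, family: str) -> list[int]:
        # No wavelet tree: the baseline iterates the member labels.
        out: set[int] = set()
        for lab in self._family_members(family):
            out.update(self.find_label(lab))
        return sorted(out)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _make_stats(lt: LabeledText, cls_a: CompressedLabelSequence,
                cls_d: CompressedLabelSequence, kind: str, k: int = 2) -> IndexStats:
    n = lt.n
    a, d = cls_a.length, cls_d.length
    labels = set(lt.labels) - {EPSILON}
    if kind == "tlbw":
        runs, boundary = cls_d.runs, cls_d.boundary
    else:
        runs, boundary = cls_a.runs, cls_a.boundary
    h0_b = empirical_entropy(boundary.bits.tolist())
    h0_r = empirical_entropy(runs)
    hk = text_entropy(lt.text.characters, k=k)
    comp = {"text": n * hk, "boundary": n * h0_b}
    if kind == "ht":
        # plain storage: runs at fixed width + one (start, end) pair per
        # labeled factor
        width = max(1, math.ceil(math.log2(max(2, len(labels) + 1))))
        nspans = sum(1 for r in runs if r != EPSILON)
        comp["runs_plain"] = a * width
        comp["span_map"] = 2 * nspans * max(1, math.ceil(math.log2(max(2, n))))
    else:
        comp["wavelet_tree"] = len(runs) * h0_r
    return IndexStats(n=n, sigma=lt.text.sigma, l=len(labels), a=a, d=d,
                      a_over_n=a / n, d_over_n=d / n, h0_runs=h0_r,
                      h0_boundary=h0_b, hk_text=hk, k=k, component_bits=comp)


def _prepare(lt: LabeledText, sample_rate: int):
    sa = build_suffix_array(lt.text)
    fm = FMIndex(lt.text, sa=sa, sample_rate=sample_rate)
    cls_a = compress_labels(lt.labels)
    cls_d = compress_labels(labels_in_bwt_order(lt, sa))
    return fm, cls_a, cls_d


def build_tl(lt: LabeledText, shape_mode: str = "auto", sample_rate: int = 32,
             hierarchy: LabelHierarchy | None = None) -> TLIndex:
    fm, cls_a, cls_d = _prepare(lt, sample_rate)
    shape = _choose_shape(cls_a.runs, shape_mode, hierarchy)
    wt = WaveletTree(cls_a.runs, shape)
    return TLIndex(fm, cls_a, wt, hierarchy, _make_stats(lt, cls_a, cls_d, "tl"))


def build_tlbw(lt: LabeledText, shape_mode: str = "auto", sample_rate: int = 32,
               hierarchy: LabelHierarchy | None = None) -> TLBWIndex:
    fm, cls_a, cls_d = _prepare(lt, sample_rate)
    shape = _choose_shape(cls_d.runs, shape_mode, hierarchy)
    wt = WaveletTree(cls_d.runs, shape)
    return TLBWIndex(fm, cls_d, wt, hierarchy,
                     _make_stats(lt, cls_a, cls_d, "tlbw"))


def build_ht(lt: LabeledText, sample_rate: int = 32,
             hierarchy: LabelHierarchy | None = None) -> HTIndex:
    fm, cls_a, cls_d = _prepare(lt, sample_rate)
    spans: dict[str, list[tuple[int, int]]] = {}
    for k, lab in enumerate(cls_a.runs):
        if lab == EPSILON:
            continue
        spans.setdefault(lab, []).append(cls_a.run_interval(k))
    return HTIndex(fm, cls_a, spans, hierarchy,
                   _make_stats(lt, cls_a, cls_d, "ht"))
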