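"""Rank/select bit vectors and shape-configurable wavelet trees.

These are the storage primitives the labeled-text indexes are assembled
from: a bit vector with constant-time rank/select (used for the run
boundary vectors over the label string) and a binary wavelet tree storing
the run-compressed label sequence, whose topology ("shape") may be
balanced, Huffman, or derived from a label hierarchy.

Conventions, fixed once for the whole package:

* ``rank(b, i)`` counts occurrences of bit ``b`` in the *inclusive*
  prefix ``B[0..i]``.
* ``select(b, j)`` takes a 1-based ordinal ``j`` and returns a 0-based
  position, so ``rank(b, select(b, j)) == j``.
"""

from __future__ import annotations

import heapq
from typing import Hashable, Iterable, Sequence

import numpy as np

Label = Hashable

__all__ = [
    "BitVector",
    "ShapeNode",
    "WTNode",
    "WaveletTree",
    "balanced_shape",
    "huffman_shape",
]


class BitVector:
    """Static bit vector with precomputed rank/select directories.

    The representation is uncompressed: a byte per bit plus a dense
    cumulative-rank directory and the positions of every set (and, lazily,
    unset) bit.  Queries are O(1) array lookups; compressed layouts could
    be swapped in behind the same contract.
    """

    __slots__ = ("bits", "_csum1", "_ones", "_zeros")

    def __init__(self, bits: Iterable[int]):
        b = np.asarray(list(bits) if not isinstance(bits, np.ndarray) else bits,
                       dtype=np.uint8)
        if b.size and (b.max() > 1):
            raise ValueError("bit vector entries must be 0 or 1")
        self.bits = b
        self._csum1 = np.cumsum(b, dtype=np.int64)
        self._ones = np.flatnonzero(b == 1)
        self._zeros: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.bits.size)

    def __getitem__(self, i: int) -> int:
        return int(self.bits[i])

    def count(self, b: int) -> int:
        """Total number of occurrences of bit ``b``."""
        n1 = int(self._ones.size)
        return n1 if b == 1 else len(self) - n1

    def rank(self, b: int, i: int) -> int:
        """Occurrences of bit ``b`` in the inclusive prefix ``B[0..i]``."""
        if not 0 <= i < len(self):
            raise IndexError(f"rank position {i} out of range [0, {len(self)})")
        return self._rank(b, i)

    def _rank(self, b: int, i: int) -> int:
        # Internal variant tolerating i == -1 (empty prefix) for interval
        # arithmetic at the left edge.
        if i < 0:
            return 0
        r1 = int(self._csum1[i])
        return r1 if b == 1 else i + 1 - r1

    def select(self, b: int, j: int) -> int:
        """Position of the ``j``-th (1-based) occurrence of bit ``b``."""
        if j < 1 or j > self.count(b):
            raise ValueError(
                f"select ordinal {j} exceeds count of bit {b} ({self.count(b)})")
        if b == 1:
            return int(self._ones[j - 1])
        if self._zeros is None:
            self._zeros = np.flatnonzero(self.bits == 0)
        return int(self._zeros[j - 1])


# ---------------------------------------------------------------------------
# Shapes: binary topologies over a label alphabet
# ---------------------------------------------------------------------------

class ShapeNode:
    """Node of a binary topology over an alphabet.

    A leaf carries a symbol; an internal node carries two children and,
    optionally, a family label (used when the shape mirrors a label
    hierarchy, so family queries can enter the tree mid-way).
    """

    __slots__ = ("symbol", "left", "right", "label")

    def __init__(self, symbol: Label = None, left: "ShapeNode | None" = None,
                 right: "ShapeNode | None" = None, label: Label = None):
        if (left is None) != (right is None):
            raise ValueError("internal shape nodes need both children")
        self.symbol = symbol
        self.left = left
        self.right = right
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaf_symbols(self) -> list[Label]:
        if self.is_leaf:
            return [self.symbol]
        return self.left.leaf_symbols() + self.right.leaf_symbols()

    def to_obj(self):
        """Plain-python form for serialization."""
        if self.is_leaf:
            obj = {"leaf": self.symbol}
            if self.label is not None:
                obj["label"] = self.label
            return obj
        return {"label": self.label,
                "left": self.left.to_obj(), "right": self.right.to_obj()}

    @classmethod
    def from_obj(cls, obj) -> "ShapeNode":
        if "leaf" in obj:
            return cls(symbol=obj["leaf"], label=obj.get("label"))
        return cls(left=cls.from_obj(obj["left"]),
                   right=cls.from_obj(obj["right"]), label=obj.get("label"))


def _key(sym: Label) -> str:
    # Deterministic ordering of mixed-type symbols (labels are usually
    # strings; "" stands for the unlabeled symbol).
    return str(sym)


def balanced_shape(symbols: Iterable[Label]) -> ShapeNode:
    """Balanced binary topology; ties broken by lexicographic label order."""
    syms = sorted(set(symbols), key=_key)
    if not syms:
        raise ValueError("cannot build a shape over an empty alphabet")

    def build(chunk: list[Label]) -> ShapeNode:
        if len(chunk) == 1:
            return ShapeNode(symbol=chunk[0])
        mid = (len(chunk) + 1) // 2
        return ShapeNode(left=build(chunk[:mid]), right=build(chunk[mid:]))

    return build(syms)


def huffman_shape(frequencies: dict) -> ShapeNode:
    """Huffman topology: frequent symbols sit closer to the root.

    Frequencies must be positive.  Ties are broken deterministically by
    insertion order of the (sorted) symbols, so the same table always
    yields the same tree.
    """
    if not frequencies:
        raise ValueError("empty frequency table")
    if any(f <= 0 for f in frequencies.values()):
        raise ValueError("frequencies must be positive")
    heap = []
    for tie, sym in enumerate(sorted(frequencies, key=_key)):
        heap.append((float(frequencies[sym]), tie, ShapeNode(symbol=sym)))
    heapq.heapify(heap)
    tie = len(heap)
    while len(heap) > 1:
        f1, _, a = heapq.heappop(heap)
        f2, _, b = heapq.heappop(heap)
        heapq.heappush(heap, (f1 + f2, tie, ShapeNode(left=a, right=b)))
        tie += 1
    return heap[0][2]


# ---------------------------------------------------------------------------
# Wavelet tree
# ---------------------------------------------------------------------------

class WTNode:
    """Wavelet-tree node.

    Internal nodes carry a bit vector routing each stored symbol left (0)
    or right (1), and may carry a family label when the shape mirrors a
    hierarchy.  Leaves carry a symbol (their label) and no bit vector.
    """

    __slots__ = ("val", "label", "left", "right", "parent", "count")

    def __init__(self):
        self.val: BitVector | None = None
        self.label: Label = None
        self.left: "WTNode | None" = None
        self.right: "WTNode | None" = None
        self.parent: "WTNode | None" = None
        self.count: int = 0  # symbols routed to this node

    @property
    def is_leaf(self) -> bool:
        return self.left is None


class WaveletTree:
    """Binary tree storing a sequence of labels, supporting access,
    per-label select, and range-restricted location of a label.

    ``descents`` counts how many root-involving location passes have been
    made (one per :meth:`positions_of` / :meth:`range_locate` /
    :meth:`positions_under` call); family queries must cost a single
    descent regardless of family size, which callers can verify from it.
    """

    def __init__(self, sequence: Sequence[Label], shape: ShapeNode | None = None):
        seq = list(sequence)
        if shape is None:
            if not seq:
                raise ValueError("an empty sequence needs an explicit shape")
            shape = balanced_shape(seq)
        self.shape = shape
        self.sequence_length = len(seq)
        self.descents = 0
        self._families: dict[Label, WTNode] = {}
        self.root = self._build(shape, seq, parent=None)
        self.leaves: dict[Label, WTNode] = {}
        self._collect(self.root)
        missing = {s for s in seq} - set(self.leaves)
        if missing:
            raise ValueError(f"symbols missing from shape: {sorted(missing, key=_key)}")

    def _build(self, shape: ShapeNode, seq: list[Label], parent) -> WTNode:
        node = WTNode()
        node.parent = parent
        node.count = len(seq)
        if shape.label is not None:
            # family name attached by a hierarchy shape (possibly on a
            # leaf, for singleton families)
            self._families[shape.label] = node
        if shape.is_leaf:
            node.label = shape.symbol
            return node
        node.label = shape.label
        leftset = set(shape.left.leaf_symbols())
        bits = [0 if s in leftset else 1 for s in seq]
        node.val = BitVector(bits)
        node.left = self._build(shape.left, [s for s in seq if s in leftset], node)
        node.right = self._build(shape.right, [s for s in seq if s not in leftset], node)
        return node

    def _collect(self, node: WTNode) -> None:
        if node.is_leaf:
            if node.label in self.leaves:
                raise ValueError(f"duplicate leaf symbol {node.label!r}")
            self.leaves[node.label] = node
        else:
            self._collect(node.left)
            self._collect(node.right)

    # -- queries -----------------------------------------------------------

    def access(self, i: int) -> Label:
        """The i-th symbol of the stored sequence, via root-to-leaf descent."""
        if not 0 <= i < self.sequence_length:
            raise IndexError(f"access position {i} out of range")
        node = self.root
        while not node.is_leaf:
            b = node.val[i]
            i = node.val.rank(b, i) - 1
            node = node.left if b == 0 else node.right
        return node.label

    def select_label(self, label: Label, i: int) -> int:
        """Position of the i-th (1-based) occurrence of ``label``."""
        leaf = self.leaves.get(label)
        if leaf is None or not 1 <= i <= leaf.count:
            raise ValueError(f"fewer than {i} occurrences of {label!r}")
        return self._to_root(leaf, i - 1)

    def _to_root(self, node: WTNode, pos: int) -> int:
        """Map a position local to ``node`` up to root coordinates."""
        while node.parent is not None:
            parent = node.parent
            b = 0 if parent.left is node else 1
            pos = parent.val.select(b, pos + 1)
            node = parent
        return pos

    def positions_of(self, label: Label) -> list[int]:
        """All positions holding ``label``, ascending; [] if absent."""
        self.descents += 1
        leaf = self.leaves.get(label)
        if leaf is None:
            return []
        return sorted(self._to_root(leaf, k) for k in range(leaf.count))

    def range_locate(self, label: Label, lo: int, hi: int) -> list[int]:
        """Positions of ``label`` within root range [lo, hi] (inclusive).

        Root-to-leaf descent narrows the interval with per-node rank;
        surviving leaf positions are mapped back to root coordinates.
        """
        self.descents += 1
        leaf = self.leaves.get(label)
        if leaf is None or lo > hi:
            return []
        node = self.root
        while not node.is_leaf:
            child = node.left if leaf_under(node.left, label) else node.right
            b = 0 if child is node.left else 1
            lo = node.val._rank(b, lo - 1)
            hi = node.val._rank(b, hi) - 1
            if lo > hi:
                return []
            node = child
        return sorted(self._to_root(node, k) for k in range(lo, hi + 1))

    def family_node(self, label: Label) -> WTNode:
        """The node (leaf or hierarchy-labelled internal) for ``label``."""
        if label in self._families:
            return self._families[label]
        if label in self.leaves:
            return self.leaves[label]
        raise KeyError(f"label or family {label!r} unknown to the shape")

    def positions_under(self, label: Label) -> list[int]:
        """Root positions of every symbol stored under ``label``'s node.

        For a family this is the union over all member labels, obtained in
        a single entry at the corresponding internal node rather than one
        descent per member.
        """
        self.descents += 1
        node = self.family_node(label)
        return sorted(self._to_root(node, k) for k in range(node.count))


def leaf_under(node: WTNode, label: Label) -> bool:
    if node.is_leaf:
        return node.label == label
    return leaf_under(node.left, label) or leaf_under(node.right, label)
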