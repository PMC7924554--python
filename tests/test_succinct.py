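"""Bit-vector rank/select and wavelet-tree behaviour against list-scan
oracles, on fixed examples and randomized/property inputs."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labelidx import (BitVector, ShapeNode, WaveletTree, balanced_shape,
                      huffman_shape)

# Boundary vectors of the three-sequence example (text order and BWT
# order), precomputed by the run-boundary rule from the label string.
B_A_BITS = [int(c) for c in "100100110010011001000"]
B_D_BITS = [int(c) for c in "111111101011111001111"]
D_RUNS = ["L2", "L1.1", "", "L3", "", "L1.1", "L1.2", "", "L2", "L1.1",
          "L3", "L1.2", "L2", "", "L3", "", "L2"]
A_RUNS = ["L1.2", "L2", "", "L3", "L1.1", "", "L2", ""]


class TestBitVector:
    def test_boundary_vector_counts(self):
        bd = BitVector(B_D_BITS)
        assert len(bd) == 21
        assert bd.rank(1, 20) == 17
        assert bd.count(0) == 4

    def test_seventh_one_bit_sits_at_position_six(self):
        # the run containing BWT row 7 starts at row 6, the 7th run start
        bd = BitVector(B_D_BITS)
        assert bd.rank(1, 6) == 7
        assert bd.select(1, 7) == 6

    def test_text_order_boundary_ranks(self):
        ba = BitVector(B_A_BITS)
        assert ba.rank(0, 9) == 6
        assert ba.select(1, 2) == 3

    def test_degenerate_vectors(self):
        assert len(BitVector([])) == 0
        assert BitVector([1] * 5).rank(1, 4) == 5
        assert BitVector([0, 0, 0]).rank(1, 2) == 0
        assert BitVector([1, 0]).select(1, 1) == 0

    def test_out_of_range_and_overlarge_ordinals_raise(self):
        bv = BitVector([1, 0, 1])
        with pytest.raises(IndexError):
            bv.rank(1, 3)
        with pytest.raises(IndexError):
            bv.rank(1, -1)
        with pytest.raises(ValueError):
            bv.select(1, 3)
        with pytest.raises(ValueError):
            bv.select(0, 2)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=300))
    def test_rank_select_inversion(self, bits):
        bv = BitVector(bits)
        for b in (0, 1):
            for j in range(1, bv.count(b) + 1):
                pos = bv.select(b, j)
                assert bv.rank(b, pos) == j
                assert bv[pos] == b

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=200),
           st.data())
    def test_rank_partition_and_prefix_scan(self, bits, data):
        bv = BitVector(bits)
        i = data.draw(st.integers(0, len(bits) - 1))
        assert bv.rank(0, i) + bv.rank(1, i) == i + 1
        assert bv.rank(1, i) == sum(bits[:i + 1])


def hierarchy_like_shape():
    l1 = ShapeNode(left=ShapeNode(symbol="L1.1"),
                   right=ShapeNode(symbol="L1.2"), label="L1")
    rest = ShapeNode(left=ShapeNode(left=ShapeNode(symbol="L2"),
                                    right=ShapeNode(symbol="L3")),
                     right=ShapeNode(symbol=""))
    return ShapeNode(left=l1, right=rest)


class TestWaveletTree:
    def test_example_tree_has_five_leaves_and_four_internal_nodes(self):
        wt = WaveletTree(A_RUNS, hierarchy_like_shape())
        assert len(wt.leaves) == 5

        def count_internal(n):
            return 0 if n.is_leaf else 1 + count_internal(n.left) + count_internal(n.right)
        assert count_internal(wt.root) == 4

    def test_example_access_and_positions(self):
        wa = WaveletTree(A_RUNS, hierarchy_like_shape())
        assert wa.access(1) == "L2"
        assert wa.positions_of("L2") == [1, 6]
        assert wa.select_label("L2", 2) == 6
        wd = WaveletTree(D_RUNS, hierarchy_like_shape())
        assert wd.access(6) == "L1.2"
        assert wd.positions_of("L1.2") == [6, 11]
        assert wd.select_label("L1.2", 2) == 11

    def test_range_locate_example(self):
        wd = WaveletTree(D_RUNS, hierarchy_like_shape())
        assert wd.range_locate("L1.2", 0, 16) == [6, 11]
        assert wd.range_locate("L1.2", 7, 10) == []
        assert wd.range_locate("L1.2", 6, 6) == [6]

    def test_single_symbol_alphabet_is_one_leaf(self):
        wt = WaveletTree(["x"] * 7)
        assert wt.root.is_leaf
        assert all(wt.access(i) == "x" for i in range(7))

    def test_absent_label_and_missing_shape_symbol(self):
        wt = WaveletTree(A_RUNS, hierarchy_like_shape())
        assert wt.positions_of("nope") == []
        with pytest.raises(ValueError):
            WaveletTree(["a", "b"], balanced_shape(["a"]))
        with pytest.raises(ValueError):
            wt.select_label("L2", 3)

    @pytest.mark.parametrize("shape_kind", ["balanced", "huffman", "given"])
    def test_agrees_with_list_scan_oracle(self, shape_kind):
        rng = random.Random(7)
        for trial in range(6):
            nsym = rng.randint(1, 32)
            syms = [f"s{i}" for i in range(nsym)]
            seq = [rng.choice(syms) for _ in range(rng.randint(1, 2000))]
            if shape_kind == "balanced":
                shape = balanced_shape(seq)
            elif shape_kind == "huffman":
                freq = {s: seq.count(s) for s in set(seq)}
                shape = (huffman_shape(freq) if len(freq) > 1
                         else ShapeNode(symbol=seq[0]))
            else:
                shape = balanced_shape(syms)  # declared-but-unused leaves ok
            wt = WaveletTree(seq, shape)
            assert [wt.access(i) for i in range(len(seq))] == seq
            for s in set(seq):
                want = [i for i, x in enumerate(seq) if x == s]
                assert wt.positions_of(s) == want
                for j, p in enumerate(want, 1):
                    assert wt.select_label(s, j) == p
            for _ in range(100):
                i = rng.randint(0, len(seq) - 1)
                j = rng.randint(i, len(seq) - 1)
                s = rng.choice(syms)
                want = [z for z in range(i, j + 1) if seq[z] == s]
                assert wt.range_locate(s, i, j) == want


class TestHuffmanShape:
    def depth(self, shape, sym, d=0):
        if shape.is_leaf:
            return d if shape.symbol == sym else None
        return (self.depth(shape.left, sym, d + 1)
                or self.depth(shape.right, sym, d + 1))

    def test_two_equal_symbols_sit_at_depth_one(self):
        s = huffman_shape({"a": 1, "b": 1})
        assert self.depth(s, "a") == 1 and self.depth(s, "b") == 1

    def test_dominant_symbol_sits_at_depth_one(self):
        s = huffman_shape({"a": 4, "b": 1, "c": 1})
        assert self.depth(s, "a") == 1

    def test_weighted_depth_never_worse_than_balanced(self):
        freq = {s: A_RUNS.count(s) for s in set(A_RUNS)}
        hufs = huffman_shape(freq)
        bals = balanced_shape(list(freq))
        whuf = sum(f * self.depth(hufs, s) for s, f in freq.items())
        wbal = sum(f * self.depth(bals, s) for s, f in freq.items())
        assert whuf <= wbal

    def test_empty_or_nonpositive_frequencies_rejected(self):
        with pytest.raises(ValueError):
            huffman_shape({})
        with pytest.raises(ValueError):
            huffman_shape({"a": 0})
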