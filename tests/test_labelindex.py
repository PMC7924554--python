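"""Label-run compression, index assembly and the five queries, checked on
the worked three-sequence collection and against brute-force scans."""

import random

import pytest

from labelidx import (ANY, EPSILON, LabeledText, LabelHierarchy, TextBuffer,
                      build_ht, build_suffix_array, build_tl, build_tlbw,
                      compress_labels, hierarchy_to_shape, labels_in_bwt_order)

from conftest import (EXAMPLE_LABELS, EXAMPLE_SEQS, NaiveLabeledOracle,
                      random_labeled_text, random_patterns)

BUILDERS = {
    "tl": lambda lt, **kw: build_tl(lt, **kw),
    "tlbw": lambda lt, **kw: build_tlbw(lt, **kw),
    "ht": lambda lt, **kw: build_ht(lt, **{k: v for k, v in kw.items()
                                           if k != "shape_mode"}),
}


def all_indexes(lt, hierarchy=None, shape_mode="auto", sample_rate=32):
    return [
        build_tl(lt, shape_mode=shape_mode, hierarchy=hierarchy,
                 sample_rate=sample_rate),
        build_tlbw(lt, shape_mode=shape_mode, hierarchy=hierarchy,
                   sample_rate=sample_rate),
        build_ht(lt, hierarchy=hierarchy, sample_rate=sample_rate),
    ]


class TestCompression:
    def test_text_order_runs(self, example_lt):
        cls = compress_labels(example_lt.labels)
        assert cls.length == 8
        assert cls.runs[1] == "L2"
        assert cls.boundary[0] == 1

    def test_all_epsilon_is_one_run(self):
        cls = compress_labels([EPSILON] * 6)
        assert cls.runs == [EPSILON]
        assert cls.boundary.bits.tolist() == [1, 0, 0, 0, 0, 0]

    def test_bwt_order_runs(self, example_lt):
        sa = build_suffix_array(example_lt.text)
        d = labels_in_bwt_order(example_lt, sa)
        assert d[0] == "L2"
        assert d[6] == "L1.2"
        cls = compress_labels(d)
        assert cls.length == 17
        assert cls.runs[6] == "L1.2" and cls.runs[11] == "L1.2"

    def test_constant_labels_in_any_order(self):
        lt = LabeledText(TextBuffer([("a", "ACAC")]),
                         ["Z"] * 4 + [EPSILON])
        sa = build_suffix_array(lt.text)
        d = labels_in_bwt_order(lt, sa)
        assert set(d) == {"Z", EPSILON}

    def test_expansion_round_trips(self, example_lt):
        assert compress_labels(example_lt.labels).expand() == example_lt.labels


class TestBuilds:
    def test_tl_wavelet_tree_has_five_leaves(self, example_lt, example_hierarchy):
        ix = build_tl(example_lt, hierarchy=example_hierarchy)
        assert len(ix.W.leaves) == 5

    def test_tlbw_run_count(self, example_lt):
        ix = build_tlbw(example_lt)
        assert ix.cls.length == 17

    def test_all_epsilon_collection(self):
        lt = LabeledText(TextBuffer([("a", "ACGT")]), [EPSILON] * 5)
        for ix in all_indexes(lt):
            assert ix.label_at(2) == EPSILON
            assert ix.find_label("nope") == []
            assert ix.find_label(EPSILON) == list(range(5))


@pytest.mark.parametrize("kind", list(BUILDERS))
class TestWorkedExampleQueries:
    @pytest.fixture
    def ix(self, kind, example_lt, example_hierarchy):
        if kind == "ht":
            return BUILDERS[kind](example_lt, hierarchy=example_hierarchy)
        return BUILDERS[kind](example_lt, hierarchy=example_hierarchy)

    def test_label_of_position(self, ix):
        assert ix.label_at(2) == "L1.2"
        assert ix.label_at(6) == EPSILON  # a terminator
        with pytest.raises(IndexError):
            ix.label_at(21)

    def test_find_pattern(self, ix):
        assert ix.find_pattern("AC") == [1, 11]
        assert ix.find_pattern("GGG") == []

    def test_find_label(self, ix):
        assert ix.find_label("L2") == [3, 4, 5, 14, 15, 16]
        assert ix.find_label("L1.2") == [0, 1, 2]
        assert ix.find_label("L3") == [7, 8, 9]
        assert ix.find_label("unknown") == []

    def test_count_and_find_pattern_label(self, ix):
        assert ix.count_pattern_label("A", "L2") == 2
        assert ix.find_pattern_label("A", "L2") == [3, 14]
        assert ix.count_pattern_label("AC", "L1.1") == 1
        assert ix.find_pattern_label("AC", "L1.1") == [11]
        assert ix.find_pattern_label("AC", "L3") == []
        assert ix.count_pattern_label("A", "absent") == 0

    def test_pattern_label_at_offset(self, ix):
        # "CA" occurs at 2 and 9; position 3 is L2, position 10 is L1.1
        assert ix.find_pattern_label_at("CA", "L2", 1) == [2]
        assert (ix.find_pattern_label_at("AC", "L1.1", 0)
                == ix.find_pattern_label("AC", "L1.1"))
        assert ix.find_pattern_label_at("CA", "L1.1", ANY) == [9]

    def test_family_query(self, ix):
        assert ix.find_family("L1") == [0, 1, 2, 10, 11, 12]
        with pytest.raises(KeyError):
            ix.find_family("L9")

    def test_stats_report_run_counts(self, ix):
        st = ix.stats()
        assert st["a"] == 8 and st["d"] == 17
        assert st["n"] == 21 and st["l"] == 4
        assert st["a"] <= st["n"] and st["d"] <= st["n"]


class TestCrossIndexAgreement:
    @pytest.mark.parametrize("shape_mode,with_hierarchy",
                             [("balanced", False), ("huffman", False),
                              ("hierarchy", True)])
    def test_agrees_with_brute_force(self, shape_mode, with_hierarchy):
        rng = random.Random(hash(shape_mode) & 0xFFFF)
        for _ in range(8):
            lt = random_labeled_text(rng, max_n=400, max_labels=8)
            oracle = NaiveLabeledOracle(lt)
            hierarchy = None
            if with_hierarchy:
                labs = lt.label_set
                half = labs[:len(labs) // 2]
                obj = {"F0": half} if half else {}
                for lab in labs[len(labs) // 2:]:
                    obj[lab] = None
                hierarchy = LabelHierarchy.from_obj(obj) if obj else None
            sm = shape_mode if hierarchy is not None or shape_mode != "hierarchy" else "auto"
            indexes = all_indexes(lt, hierarchy=hierarchy, shape_mode=sm,
                                  sample_rate=rng.choice([1, 8, 32]))
            labels = lt.label_set + [EPSILON, "bogus"]
            patterns = random_patterns(rng, lt.text.characters, 4)
            for ix in indexes:
                for t in range(0, lt.n, 7):
                    assert ix.label_at(t) == oracle.label_at(t)
                for lab in labels:
                    assert ix.find_label(lab) == oracle.find_label(lab)
                for p in patterns:
                    assert ix.find_pattern(p) == oracle.find_pattern(p)
                    for lab in labels[:4]:
                        assert (ix.find_pattern_label(p, lab)
                                == oracle.find_pattern_label(p, lab))
                        assert (ix.count_pattern_label(p, lab)
                                == oracle.count_pattern_label(p, lab))
                        k = rng.randrange(0, len(p))
                        assert (ix.find_pattern_label_at(p, lab, k)
                                == oracle.find_pattern_label_at(p, lab, k))
                        assert (ix.find_pattern_label_at(p, lab, ANY)
                                == oracle.find_pattern_label_at(p, lab, None))

    def test_label_conservation(self):
        rng = random.Random(99)
        for _ in range(5):
            lt = random_labeled_text(rng, max_n=300, max_labels=6)
            for ix in all_indexes(lt):
                total = sum(len(ix.find_label(lab))
                            for lab in lt.label_set + [EPSILON])
                assert total == lt.n

    def test_findpl_is_findp_intersect_findl(self):
        rng = random.Random(3)
        for _ in range(5):
            lt = random_labeled_text(rng, max_n=300, max_labels=6)
            for ix in all_indexes(lt):
                for p in random_patterns(rng, lt.text.characters, 3):
                    for lab in lt.label_set[:3]:
                        want = sorted(set(ix.find_pattern(p))
                                      & set(ix.find_label(lab)))
                        got = ix.find_pattern_label(p, lab)
                        assert got == want
                        assert ix.count_pattern_label(p, lab) == len(got)

    def test_tlbw_range_bound_invariant(self):
        # |Z| <= y <= occ on every combined query: run count never exceeds
        # matched positions, which never exceed pattern occurrences
        rng = random.Random(31)
        for _ in range(10):
            lt = random_labeled_text(rng, max_n=400, max_labels=8)
            ix = build_tlbw(lt)
            for p in random_patterns(rng, lt.text.characters, 5):
                for lab in lt.label_set[:3] + [EPSILON]:
                    y = ix.count_pattern_label(p, lab)
                    st = ix.last_pl_stats
                    assert st["z"] <= st["y"] <= st["occ"]
                    assert st["y"] == y


class TestHierarchyShaping:
    def test_family_subtree_covers_exactly_its_labels(self):
        h = LabelHierarchy.from_obj(
            {"L1": ["L1.1", "L1.2", "L1.3"], "L2": None, "L3": None})
        shape = hierarchy_to_shape(h)
        leaves = shape.leaf_symbols()
        assert set(leaves) == {"L1.1", "L1.2", "L1.3", "L2", "L3", EPSILON}

        def find_family(node):
            if node.label == "L1":
                return node
            if node.is_leaf:
                return None
            return find_family(node.left) or find_family(node.right)
        fam = find_family(shape)
        assert fam is not None
        assert set(fam.leaf_symbols()) == {"L1.1", "L1.2", "L1.3"}
        # family leaf-sets are contiguous under the shape
        idx = {s: i for i, s in enumerate(leaves)}
        fam_idx = sorted(idx[s] for s in fam.leaf_symbols())
        assert fam_idx == list(range(fam_idx[0], fam_idx[-1] + 1))

    def test_duplicate_label_in_two_families_rejected(self):
        with pytest.raises(ValueError):
            LabelHierarchy.from_obj({"F1": ["a", "b"], "F2": ["b"]})

    def test_nested_families_and_singletons(self):
        h = LabelHierarchy.from_obj({"G": [{"G1": ["a", "b"]}, "c"],
                                     "S": ["d"]})
        fams = h.families()
        assert fams["G"] == ["a", "b", "c"]
        assert fams["G1"] == ["a", "b"]
        assert fams["S"] == ["d"]
        seq = ["a", "b", "c", "d", "a", EPSILON]
        lt = LabeledText(TextBuffer([("r", "ACGTA")]), seq)
        tl = build_tl(lt, hierarchy=h)
        assert tl.find_family("S") == tl.find_label("d")
        assert tl.find_family("G1") == sorted(
            tl.find_label("a") + tl.find_label("b"))

    def test_family_equals_union_and_uses_one_descent(self):
        rng = random.Random(41)
        for _ in range(5):
            lt = random_labeled_text(rng, max_n=300, max_labels=8)
            labs = lt.label_set
            if len(labs) < 3:
                continue
            fam = labs[:2 + rng.randrange(len(labs) - 2)]
            obj = {"FAM": fam}
            for lab in labs[len(fam):]:
                obj[lab] = None
            h = LabelHierarchy.from_obj(obj)
            oracle = NaiveLabeledOracle(lt)
            for build in (build_tl, build_tlbw):
                ix = build(lt, hierarchy=h)
                before = ix.W.descents
                got = ix.find_family("FAM")
                assert ix.W.descents == before + 1  # one entry, not per member
                assert got == oracle.find_family(fam)


class TestLabeledTextValidation:
    def test_terminator_must_carry_epsilon(self):
        with pytest.raises(ValueError):
            LabeledText(TextBuffer([("a", "AC")]), ["X", "X", "X"])

    def test_label_length_must_match(self):
        with pytest.raises(ValueError):
            LabeledText(TextBuffer([("a", "AC")]), ["X", "X"])


class TestStats:
    def test_single_label_text(self):
        lt = LabeledText(TextBuffer([("a", "ACGT")]),
                         ["Z"] * 4 + [EPSILON])
        st = build_tl(lt).stats()
        assert st["a"] == 2  # the Z run and the terminator's ε run
        assert st["l"] == 1
        assert st["h0_boundary"] > 0

    def test_component_report_is_deterministic(self, example_lt):
        s1 = build_tlbw(example_lt).stats()
        s2 = build_tlbw(example_lt).stats()
        assert s1 == s2
        assert set(s1["component_bits"]) == {"text", "boundary", "wavelet_tree"}
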