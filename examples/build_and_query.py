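"""Build all three index kinds on a tiny labeled collection and run the
five query types.

The collection is three short DNA sequences; labels mark gene-like
segments (L1.1/L1.2 are two alleles of family L1) and ε (shown as '.')
marks unlabeled letters and terminators.
"""

from labelidx import (EPSILON, LabeledText, LabelHierarchy, TextBuffer,
                      build_ht, build_tl, build_tlbw)

seqs = [("s1", "AACAGC"), ("s2", "ATCAAC"), ("s3", "AGCTTT")]
labels = (["L1.2"] * 3 + ["L2"] * 3 + [EPSILON]
          + ["L3"] * 3 + ["L1.1"] * 3 + [EPSILON]
          + ["L2"] * 3 + [EPSILON] * 4)
lt = LabeledText(TextBuffer(seqs), labels)
hierarchy = LabelHierarchy.from_obj({"L1": ["L1.1", "L1.2"],
                                     "L2": None, "L3": None})

print(f"text T  = {lt.text.characters}   (n = {lt.n})")
print(f"labels  = {' '.join(lab or '.' for lab in labels)}")

for build in (build_tl, build_tlbw, build_ht):
    ix = build(lt, hierarchy=hierarchy)
    print(f"\n[{ix.kind}]")
    # label(t): which label sits on letter t_2?
    print("  label_at(2)                =", ix.label_at(2))
    # findP: where does the pattern AC occur?
    print("  find_pattern('AC')         =", ix.find_pattern("AC"))
    # findL: which positions carry L2?
    print("  find_label('L2')           =", ix.find_label("L2"))
    # countPL / findPL: occurrences of A that are labeled L2
    print("  count_pattern_label(A, L2) =", ix.count_pattern_label("A", "L2"))
    print("  find_pattern_label(AC, L1.1) =", ix.find_pattern_label("AC", "L1.1"))

# All three kinds answer identically; they differ in storage layout and
# in which queries they answer fastest (the BWT-order index shines on
# combined pattern+label queries).
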