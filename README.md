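# labelidx

Compressed full-text indexes for **labeled sequence collections** — texts in
which every position carries at most one annotation, such as repertoire
sequencing reads whose V(D)J gene segments are labeled with allele names, or
any DNA collection with non-overlapping functional annotations.

## The problem and the model

A labeled text is a pair (T, A): a concatenation of `$`-terminated sequences
T = t₀t₁…t₍ₙ₋₁₎ over an alphabet of size σ, and a label string
A = a₀a₁…a₍ₙ₋₁₎ with aᵢ ∈ L ∪ {ε}, where L is a set of l labels and ε marks
unlabeled positions (every terminator carries ε). Consecutive positions
usually share a label, so A is stored run-compressed: a bit vector B marks
positions where the label changes (B[0] = 1, B[i] = 1 iff aᵢ ≠ a₍ᵢ₋₁₎) and
the labels at the 1-bits form the *compressed label sequence*, kept in a
wavelet tree W supporting access, per-label select and range-restricted
location in O(log l) per step.

Two index layouts are provided, plus a baseline:

* **TL-index** (U, B_A, W_A): the text in an FM-index over its
  Burrows–Wheeler transform U, plus the label runs **in text order** (A′).
  Size ≈ nH_k(T) + nH₀(B_A) + aH₀(A′) bits, with a = |A′|.
* **TL_BW-index** (U, B_D, W_D): the label of each BWT character, i.e.
  D[r] = A[SA[r]−1], run-compressed **in BWT order** (D′, d = |D′|). Since
  the BWT groups equal contexts, equal labels cluster and combined
  pattern+label queries become a single two-dimensional range query
  [L, L] × [i′, j′] inside W_D instead of locating every pattern occurrence.
* **HT-index**: baseline storing a map label → (start, end) spans plus the
  run labels in plain form.

All three answer the same queries: `label_at(t)` (the label on letter t),
`find_pattern(P)` (backward search + locate), `find_label(L)`,
`count_pattern_label(P, L)` / `find_pattern_label(P, L)` (positions labeled L
that begin an occurrence of P), the offset variants (label required at the
k-th pattern position, or anywhere in the occurrence window), and
`find_family(F)` for label hierarchies: shaping W after an n-ary hierarchy
maps each family to one internal node, so a family query costs a single
descent instead of one per member. A Huffman shape is available when query
speed/space matter more than family addressing.

## Worked example

```python
from labelidx import (EPSILON, LabeledText, LabelHierarchy, TextBuffer,
                      build_tl, build_tlbw)

seqs = [("s1", "AACAGC"), ("s2", "ATCAAC"), ("s3", "AGCTTT")]
labels = (["L1.2"]*3 + ["L2"]*3 + [EPSILON] + ["L3"]*3 + ["L1.1"]*3
          + [EPSILON] + ["L2"]*3 + [EPSILON]*4)
lt = LabeledText(TextBuffer(seqs), labels)
h = LabelHierarchy.from_obj({"L1": ["L1.1", "L1.2"], "L2": None, "L3": None})

tl = build_tl(lt, hierarchy=h)
tl.label_at(2)                    # 'L1.2'  — the label on letter t_2
tl.find_pattern("AC")             # [1, 11] — occurrences of AC
tl.find_label("L2")               # [3, 4, 5, 14, 15, 16]
tl.count_pattern_label("A", "L2") # 2       — A's at positions 3 and 14
tl.find_family("L1")              # [0, 1, 2, 10, 11, 12]

bw = build_tlbw(lt, hierarchy=h)
bw.W.positions_of("L1.2")         # [6, 11] — L1.2's runs in BWT order
bw.find_label("L1.2")             # [0, 1, 2] — mapped back to text order
```

On this collection the boundary vectors hold a = 8 text-order runs and
d = 17 BWT-order runs (`tl.stats()`), and the wavelet tree shaped by the
hierarchy has five leaves (L1.1, L1.2, L2, L3, ε). The scripts under
`examples/` walk through building and querying, hierarchy shaping, the
V(D)J read simulator, and the entropy-based size report; each prints the
numbers above (or its own) with a note on what they mean.

A thin CLI mirrors the library:

```bash
labelidx build --fasta reads.fasta --bed labels.bed --kind tlbw --out ix.json
labelidx query findpl ix.json ACG V5*01
labelidx synth vdj --reads 100 --out-prefix sim
labelidx stats ix.json
```

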