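# Methods

## Model

A labeled text is (T, A): T concatenates `$`-terminated sequences
(n characters total, alphabet size σ counting `$`), and A assigns each
position one label from L ∪ {ε}. The model is strictly non-overlapping —
one label per position — and every terminator carries ε. Annotations that
would overlap, or place a label on a terminator, are rejected at ingestion
rather than silently split, because splitting would change query semantics.

Conventions fixed package-wide:

* `rank(b, i, B)` counts bit b in the **inclusive** prefix B[0..i];
  `select(b, j, B)` takes a 1-based ordinal and returns a 0-based position,
  so `rank(b, select(b, j)) = j`.
* All positions and intervals are 0-based and inclusive on both ends;
  BED input is half-open 0-based and converted once at the boundary.
* Multi-string suffix order: the terminator of sequence k sorts before that
  of sequence k+1, and all terminators sort before alphabet letters. Row 0's
  BWT character wraps to the global last character. Internally each
  terminator is a distinct integer symbol, which keeps LF a true permutation
  (LF from the row holding terminator k lands on row k); the exposed BWT
  string writes all terminators uniformly as `$`.

## Structures

**FM-index.** Suffix array by prefix doubling (numpy lexsort,
O(n log² n)); a naive suffix sort serves as the independent oracle in
tests. C and Occ are dense per-letter cumulative tables. The suffix array
is sampled at every text position divisible by `sample_rate` (default 32,
a build parameter trading locate time for space) plus every terminator
position, so `locate` and the inverse mapping `row_of_text_position`
LF-step at most `sample_rate` times.

**Bit vectors.** Uncompressed with precomputed rank directories and select
position lists; the rank/select contract is representation-free, so an
entropy-compressed layout could be swapped in without touching callers.
Sizes are *reported* via empirical entropies rather than enforced by a
compressed layout.

**Wavelet tree.** Built over the run labels under a configurable binary
topology: `balanced` (ties broken lexicographically, for determinism),
`huffman` over run frequencies (frequent labels near the root; ties broken
by sorted insertion order so builds are reproducible), or `hierarchy`
(each n-ary family becomes a binary subtree whose root carries the family
name; a singleton family aliases its member's leaf). Default: hierarchy if
one is supplied, else Huffman. Labels declared in a shape but absent from
the sequence are legal leaves; queries for unknown labels return empty
rather than raising.

## Queries

`label_at`: rank into the boundary vector, then one wavelet-tree access
(TL); the BWT-order index first converts t to the row whose BWT character
is t (SA[row] = t+1). `find_label`: wavelet-tree positions of the label,
each mapped through select on the boundary vector and expanded over the
following 0-bits; the BWT-order index then locates each row back to text
order (the character at row r sits at text position SA[r]−1).

**Combined pattern+label queries.** For TL and HT: backward-search the
pattern, locate each occurrence, test its label. For TL_BW the query is a
range-restricted wavelet-tree location. One subtlety is load-bearing here:
D labels the *BWT characters*, i.e. D[r] = A[SA[r]−1], while the query
asks for the label **at** each occurrence start p. The rows whose BWT
character is t_p for occurrences p of P are exactly the rows in the
interval of P[1:] whose BWT character equals P[0] (the LF step maps them
one-to-one onto the interval of P). The implementation therefore runs the
range query [L, L] × [i′, j′] over the interval of P[1:], expands each hit
through select on B_D, **clamps** each run to the interval (the first and
last runs may straddle it), and filters run positions on BWT character
= P[0] via the Occ table / a scan of the BWT slice. For |P| = 1 the outer
interval is the whole BWT. Surviving rows map to text positions SA[r]−1.
The bound (contributing runs) ≤ (matched positions) ≤ (occurrences of P)
is asserted on every call and exposed as `last_pl_stats`.

Offset variants: a fixed offset k checks `label_at(p+k)` per occurrence;
the "anywhere" variant on the TL-index needs only the two boundary ranks
of the window ends — the labels inside [p, p+|P|−1] are exactly the runs
run_of(p)..run_of(p+|P|−1) — and one range-locate decides membership.

Family queries enter the wavelet tree at the family's node and map every
symbol under it back to root coordinates: one descent regardless of family
size (the tree counts descents, and tests assert the count). The HT
baseline has no wavelet tree and answers families as a member union.

## Size report

`stats()` reports n, σ, l, the run counts a (text order) and d (BWT
order) with their ratios to n, H₀ of the run sequence and of the boundary
bits, an order-k empirical entropy of T (k = 2 by default; a plug-in
estimate from k-context letter distributions), and entropy-based component
estimates in bits: n·H_k(T), n·H₀(B), and a·H₀(A′) (d·H₀(D′) for the
BWT-order index; plain-width runs plus a span map for the baseline). These
are reporting quantities, not enforced layouts.

## Serialization

A versioned JSON container (magic + version + kind header) holding the BWT
string with the terminator order, the suffix-array samples, boundary bits,
run labels, shape, optional hierarchy, and the span map for the baseline.
Loading reconstructs all support structures without the original FASTA/BED
and answers every query identically (tested). Kind and version mismatches
and truncation raise clean errors.

## Synthetic generators

Three dataset classes cover the regimes the indexes target; all are
deterministic under a fixed seed and emit valid labeled texts (ε on
terminators, no block crossing a terminator).

* **Random** (`gen_random`): iid uniform letters; label placement is a
  stationary two-state Markov chain per position, giving geometric block
  lengths with the requested mean and an expected labeled fraction exactly
  equal to the request at every position (no boundary bias from the short
  sequences). Defaults: 50-letter sequences, 1,000 labels, mean length
  12.6, 47% labeled — the hard-to-compress regime where BWT-order runs
  approach 0.8n.
* **Fixed patterns** (`gen_fixed_labels`): each label owns one reference
  pattern; placements copy it with per-letter substitution probability
  `variation_rate` (substitutions always change the letter, so the
  realized mismatch rate is calibrated: 5% ± 1% is verified at n = 10⁵).
  Gaps are geometric with mean patlen·(1−f)/f, the simplest one-parameter
  family matching a target density f; f = 1 labels every letter. Blocks
  truncate at sequence ends; placements (start, length, label, offset) are
  recorded on the returned object for calibration checks, since adjacent
  same-label blocks merge into one run in A.
* **V(D)J reads** (`gen_vdj`): trimmed V + insert (+ trimmed D + insert)
  + trimmed J, uniform substitution errors on gene-derived segments (rates
  up to ~15% are realistic for amplified repertoire data), allele-name
  labels, and a recombination string per read (`V4*02 4/ACGT/0 J1*12`:
  trims flank each junction's insert). The bundled register is ~20 V /
  5 D / 10 J *fabricated* sequences (V 150–300 bp, D 50–80, J 50–70) with
  realistic-looking allele names — synthetic by construction, not curated
  germline data; real registers load from FASTA into the same structure.
  Reads are redrawn (bounded retries) until their length falls in the
  requested window.

What the generators do **not** emulate: biologically calibrated gene-usage
frequencies, indels or position-dependent error profiles, shared homology
between register genes, or quality values. Passing tests therefore
demonstrate index correctness and calibration on these statistical
regimes, not concordance with any particular sequencing protocol.

## Problem sizes and numerical choices

The randomized suites use 100 labeled texts up to n = 2,000 with up to 20
labels for cross-index/brute-force agreement, 200 random collections for
suffix-array/BWT oracles, and n = 10⁵ for generator calibration — sizes
chosen so the full suite runs in well under a minute on one core while
still exercising multi-sequence, multi-run, and empty-result paths.
Degenerate inputs are pinned by tests: empty bit vectors, single-symbol
alphabets (a one-leaf wavelet tree), all-ε label strings, absent labels
and patterns, out-of-range positions (errors), and select ordinals beyond
the population count (errors, distinct from valid positions).

## Known limitations

* Rank/select directories are uncompressed (O(n) words); entropy bounds
  are reported, not realized.
* No streaming/appendable BWT; indexes are rebuilt, not updated.
* The O(|P| + log l) counting variant that skips boundary bits (at the
  cost of slower find) is deliberately not implemented; the structure
  favors position-reporting queries.
* Family queries on the HT baseline iterate members (it has no tree).
* `find_pattern_label_at` resolves the offset via per-occurrence label
  lookups; only the "anywhere" variant on the TL-index uses the
  two-boundary shortcut.
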