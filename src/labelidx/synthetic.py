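"""Synthetic labeled-text generators.

Three dataset classes mirror the evaluation conditions the indexes are
meant for: (1) random sequences with randomly placed random labels,
(2) random sequences in which every label always annotates (a noisy copy
of) the same reference pattern, with controllable labeled fraction,
per-letter variation, pattern length and label count, and (3) V(D)J-like
reads, each the concatenation of a trimmed V gene, a random insert,
optionally a trimmed D gene and second insert, and a trimmed J gene,
with the gene-derived segments labeled by allele name and a
recombination string (``V4*02 4/ACGT/0 J1*12``) emitted per read.

Label blocks are placed by alternating geometric gaps and blocks, so the
expected labeled fraction equals the requested one; blocks never cross a
sequence terminator.  All generators are deterministic under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fmindex import TextBuffer
from .index import EPSILON, LabeledText

__all__ = ["GeneratorConfig", "GeneRegister", "default_register",
           "gen_random", "gen_fixed_labels", "gen_vdj"]


@dataclass
class GeneratorConfig:
    """Knobs shared by the random and fixed-pattern generators.

    Defaults follow the random-dataset conditions (50-letter sequences,
    1,000 unique labels of mean length 12.6 covering 47% of the letters),
    at a total length suited to in-memory experimentation.
    """

    total_length: int = 100_000
    sequence_length: int = 50
    alphabet: str = "ACGT"
    unique_label_count: int = 1000
    mean_label_length: float = 12.6
    labeled_fraction: float = 0.47
    variation_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.total_length <= 0 or self.sequence_length <= 0:
            raise ValueError("lengths must be positive")
        if self.unique_label_count <= 0:
            raise ValueError("need at least one label")
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must lie in [0, 1]")
        if not 0.0 <= self.variation_rate <= 1.0:
            raise ValueError("variation_rate must lie in [0, 1]")
        if self.mean_label_length < 1:
            raise ValueError("mean label length must be >= 1")
        if self.mean_label_length > self.sequence_length:
            raise ValueError("labels cannot be longer than a sequence")


def _label_names(count: int) -> list[str]:
    width = len(str(count - 1))
    return [f"L{str(i).zfill(width)}" for i in range(count)]


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> list[str]:
    return [alphabet[k] for k in rng.integers(0, len(alphabet), size=length)]


def _gap_length(rng, mean_gap: float) -> int:
    if mean_gap <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean_gap + 1.0))) - 1


def _sequence_records(cfg: GeneratorConfig) -> list[tuple[str, int]]:
    """(record_id, length) pairs covering cfg.total_length letters."""
    out = []
    remaining = cfg.total_length
    k = 0
    while remaining > 0:
        length = min(cfg.sequence_length, remaining)
        out.append((f"seq{k:06d}", length))
        remaining -= length
        k += 1
    return out


def gen_random(cfg: GeneratorConfig) -> LabeledText:
    """Random letters with randomly placed, randomly named label blocks.

    Placement is a stationary two-state chain over positions: blocks have
    geometric length with the requested mean and the stationary labeled
    fraction equals ``labeled_fraction`` at every position, so sequence
    boundaries introduce no density bias.  Blocks never span a
    terminator; each sequence restarts the chain from stationarity.
    """
    rng = np.random.default_rng(cfg.seed)
    names = _label_names(cfg.unique_label_count)
    f = cfg.labeled_fraction
    m = float(cfg.mean_label_length)
    p_end = 1.0 / m  # block termination hazard -> geometric(mean m) lengths
    # gap->block hazard balancing the stationary flow f*p_end = (1-f)*q
    q = 0.0 if f == 0.0 else (1.0 if f >= 1.0 else min(1.0, f * p_end / (1.0 - f)))

    def new_label() -> str:
        return names[int(rng.integers(0, len(names)))]

    seqs, labels = [], []
    for rid, length in _sequence_records(cfg):
        letters = _random_seq(rng, cfg.alphabet, length)
        labs = [EPSILON] * length
        labeled = bool(rng.random() < f)
        lab = new_label() if labeled else EPSILON
        for p in range(length):
            if labeled:
                labs[p] = lab
                if rng.random() < p_end:  # block ends after this position
                    if f >= 1.0:
                        lab = new_label()
                    else:
                        labeled = False
            elif f > 0.0 and rng.random() < q:
                labeled = True
                lab = new_label()
        seqs.append((rid, "".join(letters)))
        labels.extend(labs + [EPSILON])  # terminator carries ε
    return LabeledText(TextBuffer(seqs), labels)


def gen_fixed_labels(cfg: GeneratorConfig | None = None, **kw) -> LabeledText:
    """Each label owns one reference pattern; placements copy it with
    per-letter substitution probability ``variation_rate``.

    Defaults (100 labels, length-25 patterns, everything labeled, 5%
    variation) follow the first fixed-label evaluation condition.
    """
    if cfg is None:
        cfg = GeneratorConfig(unique_label_count=100, mean_label_length=25,
                              labeled_fraction=1.0, variation_rate=0.05, **kw)
    rng = np.random.default_rng(cfg.seed)
    names = _label_names(cfg.unique_label_count)
    patlen = max(1, round(cfg.mean_label_length))
    alphabet = cfg.alphabet
    patterns = {name: _random_seq(rng, alphabet, patlen) for name in names}
    f = cfg.labeled_fraction
    mean_gap = None if f == 0 else patlen * (1.0 - f) / f
    others = {c: [o for o in alphabet if o != c] for c in alphabet}
    seqs, labels = [], []
    placements: list[tuple[int, int, str, int]] = []
    global_base = 0
    for seq_no, (rid, length) in enumerate(_sequence_records(cfg)):
        letters = _random_seq(rng, alphabet, length)
        labs = [EPSILON] * length
        if f > 0:
            pos = _gap_length(rng, mean_gap)
            while pos < length:
                lab = names[int(rng.integers(0, len(names)))]
                pat = patterns[lab]
                end = min(pos + patlen, length)  # truncated at the terminator
                for k, p in enumerate(range(pos, end)):
                    c = pat[k]
                    if cfg.variation_rate > 0 and rng.random() < cfg.variation_rate:
                        alts = others[c]
                        c = alts[int(rng.integers(0, len(alts)))]
                    letters[p] = c
                    labs[p] = lab
                placements.append((global_base + pos, end - pos, lab, 0))
                pos = end + _gap_length(rng, mean_gap)
        seqs.append((rid, "".join(letters)))
        labels.extend(labs + [EPSILON])
        global_base += length + 1
    lt = LabeledText(TextBuffer(seqs), labels)
    lt.reference_patterns = {k: "".join(v) for k, v in patterns.items()}
    # (global_start, length, label, offset-into-pattern) of every block,
    # for calibration checks; adjacent same-label blocks merge in A
    lt.placements = placements
    return lt


# ---------------------------------------------------------------------------
# V(D)J-like reads
# ---------------------------------------------------------------------------

@dataclass
class GeneRegister:
    """Named gene sequences grouped into V / D / J families."""

    v: dict[str, str] = field(default_factory=dict)
    d: dict[str, str] = field(default_factory=dict)
    j: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        names = list(self.v) + list(self.d) + list(self.j)
        if len(names) != len(set(names)):
            raise ValueError("gene names must be unique across families")
        for name, seq in self.all_genes().items():
            if not seq:
                raise ValueError(f"gene {name!r} has an empty sequence")

    def all_genes(self) -> dict[str, str]:
        return {**self.v, **self.d, **self.j}

    def gene_lengths(self) -> dict[str, int]:
        return {k: len(s) for k, s in self.all_genes().items()}


def default_register() -> GeneRegister:
    """A small fabricated register: ~20 V / 5 D / 10 J genes (50-300 bp)
    with realistic-looking allele names.

    The sequences are synthetic (generated from a fixed internal seed),
    not curated germline data; real registers can be loaded from FASTA
    and passed in the same structure.
    """
    rng = np.random.default_rng(148)
    alphabet = "ACGT"

    def make(prefix, count, lo, hi, alleles=2):
        genes = {}
        for i in range(count):
            allele = 1 + (i % alleles)
            name = f"{prefix}{i + 1}*{allele:02d}"
            length = int(rng.integers(lo, hi + 1))
            genes[name] = "".join(_random_seq(rng, alphabet, length))
        return genes

    return GeneRegister(v=make("V", 20, 150, 300),
                        d=make("D", 5, 50, 80),
                        j=make("J", 10, 50, 70))


def gen_vdj(register: GeneRegister | None = None, reads: int = 200,
            read_length: tuple[int, int] = (100, 350),
            variation_rate: float = 0.05, seed: int = 0,
            max_trim: int = 10, max_insert: int = 10,
            ) -> tuple[LabeledText, list[tuple[str, str]]]:
    """Simulated repertoire reads with two (VJ) or three (VDJ) labels.

    Each read is a trimmed V gene, a random insert, optionally a trimmed
    D gene plus a second insert, and a trimmed J gene; per-letter
    substitutions at ``variation_rate`` emulate amplification and
    sequencing errors (rates up to ~0.15 are typical).  Returns the
    labeled text plus one recombination string per read.
    """
    if register is None:
        register = default_register()
    if not register.v or not register.j:
        raise ValueError("register needs at least one V and one J gene")
    if not 0.0 <= variation_rate <= 1.0:
        raise ValueError("variation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    alphabet = "ACGT"
    others = {c: [o for o in alphabet if o != c] for c in alphabet}
    vnames, dnames, jnames = (sorted(register.v), sorted(register.d),
                              sorted(register.j))
    lo, hi = read_length

    def mutate(seg: str) -> str:
        if variation_rate == 0:
            return seg
        out = list(seg)
        for k, c in enumerate(out):
            if rng.random() < variation_rate:
                out[k] = others[c][int(rng.integers(0, 3))]
        return "".join(out)

    seqs, labels, annotations = [], [], []
    for r in range(reads):
        for _attempt in range(40):
            use_d = bool(dnames) and bool(rng.integers(0, 2))
            vn = vnames[int(rng.integers(0, len(vnames)))]
            jn = jnames[int(rng.integers(0, len(jnames)))]
            vseq, jseq = register.v[vn], register.j[jn]
            del_v = int(rng.integers(0, min(max_trim + 1, len(vseq))))
            del_j = int(rng.integers(0, min(max_trim + 1, len(jseq))))
            ins1 = "".join(_random_seq(
                rng, alphabet, int(rng.integers(0, max_insert + 1))))
            segments = [(vn, vseq[:len(vseq) - del_v]), (None, ins1)]
            if use_d:
                dn = dnames[int(rng.integers(0, len(dnames)))]
                dseq = register.d[dn]
                d_trim = min(max_trim, 5)
                d5 = int(rng.integers(0, min(d_trim + 1, len(dseq))))
                d3 = int(rng.integers(0, min(d_trim + 1, max(1, len(dseq) - d5))))
                dcore = dseq[d5:len(dseq) - d3]
                if not dcore:
                    continue
                ins2 = "".join(_random_seq(
                    rng, alphabet, int(rng.integers(0, max_insert + 1))))
                segments += [(dn, dcore), (None, ins2)]
                ann = f"{vn} {del_v}/{ins1}/{d5} {dn} {d3}/{ins2}/{del_j} {jn}"
            else:
                ann = f"{vn} {del_v}/{ins1}/{del_j} {jn}"
            segments.append((jn, jseq[del_j:]))
            total = sum(len(s) for _, s in segments)
            if lo <= total <= hi:
                break
        rid = f"read{r:06d}"
        read_chars, read_labels = [], []
        for lab, seg in segments:
            seg = mutate(seg) if lab is not None else seg
            read_chars.append(seg)
            read_labels.extend([lab if lab is not None else EPSILON] * len(seg))
        seqs.append((rid, "".join(read_chars)))
        labels.extend(read_labels + [EPSILON])
        annotations.append((rid, ann))
    text = TextBuffer(seqs)
    return LabeledText(text, labels), annotations
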