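"""Readers, writers and index serialization.

Input convention: sequences come from a multi-record FASTA (each record
becomes one ``$``-terminated sequence) and label annotations from a BED
file (record id, half-open 0-based ``start``/``end``, label name).
Annotations must not overlap and must not cross record boundaries; every
position not covered by an annotation carries ε.

Indexes serialize to a versioned JSON container; loading it back answers
all queries identically and never needs the original FASTA/BED.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from .fmindex import FMIndex, TextBuffer, _TextMeta
from .index import (EPSILON, CompressedLabelSequence, HTIndex, IndexStats,
                    LabeledText, LabelHierarchy, TLBWIndex, TLIndex)
from .succinct import BitVector, ShapeNode, WaveletTree

MAGIC = "labelidx"
VERSION = 1

__all__ = [
    "AnnotationRecord", "read_labeled_input", "write_labeled_text",
    "parse_vdj_annotation", "read_vdj_annotations", "write_vdj_annotations",
    "load_hierarchy", "save_hierarchy", "save_index", "load_index",
]


@dataclass(frozen=True)
class AnnotationRecord:
    """One labeled span: half-open 0-based [start, end) within a record."""

    record_id: str
    start: int
    end: int
    label: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if not self.label or self.label == EPSILON:
            raise ValueError("annotation label must be non-empty")


# ---------------------------------------------------------------------------
# FASTA + BED ingestion
# ---------------------------------------------------------------------------

def read_bed(path) -> list[AnnotationRecord]:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{ln}: need 4 BED columns (id, start, end, name)")
            records.append(AnnotationRecord(fields[0], int(fields[1]),
                                            int(fields[2]), fields[3]))
    return records


def read_labeled_input(fasta_path, bed_path=None) -> LabeledText:
    """Assemble a :class:`LabeledText` from a FASTA and an optional BED."""
    seqs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta_path), "fasta")]
    text = TextBuffer(seqs)
    labels = [EPSILON] * text.n
    if bed_path is not None:
        annots = bed_path if isinstance(bed_path, list) else read_bed(bed_path)
        starts = dict(zip(text.record_ids, text.sequence_boundaries))
        lengths = {rid: len(s) for rid, s in seqs}
        by_id: dict[str, list[AnnotationRecord]] = {}
        for a in annots:
            if a.record_id not in starts:
                raise ValueError(f"BED record id {a.record_id!r} not in FASTA")
            if a.end > lengths[a.record_id]:
                raise ValueError(
                    f"span [{a.start}, {a.end}) exceeds record {a.record_id!r} "
                    f"of length {lengths[a.record_id]}")
            by_id.setdefault(a.record_id, []).append(a)
        for rid, items in by_id.items():
            items.sort(key=lambda a: (a.start, a.end))
            for prev, cur in zip(items, items[1:]):
                if cur.start < prev.end:
                    raise ValueError(
                        f"overlapping annotations on {rid!r}: "
                        f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})")
            base = starts[rid]
            for a in items:
                for p in range(base + a.start, base + a.end):
                    labels[p] = a.label
    return LabeledText(text, labels)


def write_labeled_text(lt: LabeledText, fasta_path, bed_path) -> None:
    """Inverse of :func:`read_labeled_input` (identity on (T, A))."""
    text = lt.text
    with open(fasta_path, "w") as fa:
        for k, rid in enumerate(text.record_ids):
            start = text.sequence_boundaries[k]
            end = (text.sequence_boundaries[k + 1]
                   if k + 1 < text.num_sequences else text.n)
            fa.write(f">{rid}\n{text.characters[start:end - 1]}\n")
    with open(bed_path, "w") as bed:
        for a in annotations_of(lt):
            bed.write(f"{a.record_id}\t{a.start}\t{a.end}\t{a.label}\n")


def annotations_of(lt: LabeledText) -> list[AnnotationRecord]:
    """The labeled runs of a labeled text as BED-style records."""
    out = []
    text = lt.text
    i = 0
    while i < lt.n:
        lab = lt.labels[i]
        j = i
        while j + 1 < lt.n and lt.labels[j + 1] == lab:
            j += 1
        if lab != EPSILON:
            rid, off = text.record_of(i)
            rid2, off2 = text.record_of(j)
            if rid != rid2:
                raise ValueError("label run crosses a record boundary")
            out.append(AnnotationRecord(rid, off, off2 + 1, lab))
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# V(D)J recombination annotation strings
# ---------------------------------------------------------------------------

def parse_vdj_annotation(s: str, gene_lengths: dict[str, int],
                         record_id: str = "") -> list[AnnotationRecord]:
    """Parse a recombination string into labeled spans.

    ``"V4*02 4/ACGT/0 J1*12"`` means: the V4*02 gene minus its 4 last
    letters, then the insert ACGT, then the J1*12 gene minus its 0 first
    letters.  A three-gene form inserts a D segment with a junction
    string on each side: ``"V a/ins/b D c/ins/d J"`` trims ``a`` letters
    off V's end, ``b`` off D's start, ``c`` off D's end and ``d`` off J's
    start.
    """
    tokens = s.split()
    if len(tokens) not in (3, 5):
        raise ValueError(f"malformed recombination string {s!r}")
    genes = tokens[0::2]
    junctions = tokens[1::2]
    for g in genes:
        if g not in gene_lengths:
            raise ValueError(f"unknown gene {g!r} in {s!r}")
    trims: list[tuple[int, str, int]] = []
    for j in junctions:
        parts = j.split("/")
        if len(parts) != 3:
            raise ValueError(f"malformed junction {j!r} in {s!r}")
        try:
            left, right = int(parts[0]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"malformed junction {j!r} in {s!r}") from exc
        trims.append((left, parts[1], right))
    spans = []
    pos = 0
    # trims[k] sits between genes[k] and genes[k+1]
    for k, g in enumerate(genes):
        length = gene_lengths[g]
        cut_start = trims[k - 1][2] if k > 0 else 0
        cut_end = trims[k][0] if k < len(trims) else 0
        seg = length - cut_start - cut_end
        if seg <= 0:
            raise ValueError(f"gene {g!r} fully trimmed away in {s!r}")
        spans.append(AnnotationRecord(record_id, pos, pos + seg, g))
        pos += seg
        if k < len(trims):
            pos += len(trims[k][1])  # unlabeled insert
    return spans


def write_vdj_annotations(path, annotations: list[tuple[str, str]]) -> None:
    """Sidecar file: one ``record_id<TAB>recombination-string`` per line."""
    with open(path, "w") as fh:
        for rid, ann in annotations:
            fh.write(f"{rid}\t{ann}\n")


def read_vdj_annotations(path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                rid, ann = line.split("\t", 1)
                out.append((rid, ann))
    return out


# ---------------------------------------------------------------------------
# Hierarchy config
# ---------------------------------------------------------------------------

def load_hierarchy(path) -> LabelHierarchy:
    with open(path) as fh:
        return LabelHierarchy.from_obj(yaml.safe_load(fh))


def save_hierarchy(h: LabelHierarchy, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(h.to_obj(), fh)


# ---------------------------------------------------------------------------
# Index serialization
# ---------------------------------------------------------------------------

def _fm_to_obj(fm: FMIndex) -> dict:
    meta = fm.text_meta
    return {
        "record_ids": meta.record_ids,
        "sequence_boundaries": meta.sequence_boundaries,
        "alphabet": meta.alphabet,
        "n": meta.n,
        "bwt": fm.bwt,
        "bwt_sent_ids": [int(c) for c in fm.bwt_ints if c < fm.nsent],
        "sa_samples": {str(k): v for k, v in fm.sa_samples.items()},
        "sample_rate": fm.sample_rate,
    }


def _fm_from_obj(obj: dict) -> FMIndex:
    meta = _TextMeta(obj["record_ids"], obj["sequence_boundaries"],
                     obj["alphabet"], obj["n"])
    nsent = meta.num_sequences
    code = {ch: nsent + i for i, ch in enumerate(meta.alphabet)}
    sent_iter = iter(obj["bwt_sent_ids"])
    ints = np.empty(meta.n, dtype=np.int64)
    for i, ch in enumerate(obj["bwt"]):
        ints[i] = next(sent_iter) if ch == "$" else code[ch]
    samples = {int(k): int(v) for k, v in obj["sa_samples"].items()}
    return FMIndex.from_parts(meta, ints, samples, int(obj["sample_rate"]))


def _cls_to_obj(cls: CompressedLabelSequence) -> dict:
    return {"boundary": "".join(map(str, cls.boundary.bits.tolist())),
            "runs": cls.runs}


def _cls_from_obj(obj: dict) -> CompressedLabelSequence:
    return CompressedLabelSequence(
        BitVector([int(c) for c in obj["boundary"]]), list(obj["runs"]))


def save_index(ix, path) -> None:
    obj = {
        "magic": MAGIC,
        "version": VERSION,
        "kind": ix.kind,
        "fm": _fm_to_obj(ix.fm),
        "stats": ix.stats(),
        "hierarchy": ix.hierarchy.to_obj() if ix.hierarchy is not None else None,
    }
    if ix.kind in ("tl", "tlbw"):
        obj["cls"] = _cls_to_obj(ix.cls)
        obj["shape"] = ix.W.shape.to_obj()
    elif ix.kind == "ht":
        obj["cls"] = _cls_to_obj(ix.cls)
        obj["label_spans"] = {lab: [list(sp) for sp in spans]
                              for lab, spans in ix.label_spans.items()}
    else:  # pragma: no cover - unreachable
        raise ValueError(f"unknown index kind {ix.kind!r}")
    Path(path).write_text(json.dumps(obj))


def load_index(path, kind: str | None = None):
    """Load a serialized index; ``kind`` guards against loading the wrong
    container kind (e.g. a tl blob where a tlbw index is expected)."""
    try:
        obj = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupt index file {path}: {exc}") from exc
    if not isinstance(obj, dict) or obj.get("magic") != MAGIC:
        raise ValueError(f"{path} is not a labelidx index container")
    if obj.get("version") != VERSION:
        raise ValueError(f"unsupported index version {obj.get('version')!r}")
    if kind is not None and obj["kind"] != kind:
        raise ValueError(f"index kind mismatch: file holds {obj['kind']!r}, "
                         f"expected {kind!r}")
    fm = _fm_from_obj(obj["fm"])
    hier = (LabelHierarchy.from_obj(obj["hierarchy"])
            if obj.get("hierarchy") is not None else None)
    st = obj["stats"]
    stats = IndexStats(n=st["n"], sigma=st["sigma"], l=st["l"], a=st["a"],
                       d=st["d"], a_over_n=st["a_over_n"],
                       d_over_n=st["d_over_n"], h0_runs=st["h0_runs"],
                       h0_boundary=st["h0_boundary"], hk_text=st["hk_text"],
                       k=st["k"], component_bits=st["component_bits"])
    cls = _cls_from_obj(obj["cls"])
    if obj["kind"] == "ht":
        spans = {lab: [tuple(sp) for sp in sps]
                 for lab, sps in obj["label_spans"].items()}
        return HTIndex(fm, cls, spans, hier, stats)
    shape = ShapeNode.from_obj(obj["shape"])
    wt = WaveletTree(cls.runs, shape)
    klass = TLIndex if obj["kind"] == "tl" else TLBWIndex
    return klass(fm, cls, wt, hier, stats)
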