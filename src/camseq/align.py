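"""Collapsed-alphabet alignment of A-to-G converted reads and A-site pileup.

Because the chemistry reads every unmodified A as G, alignment must be
blind to A/G differences on the sense strand (and, symmetrically, to T/C
differences when the sense strand is the reverse complement of the
reference). Reads and references are therefore compared in a three-letter
collapsed space, exactly as bisulfite aligners collapse C/T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_COLLAPSE_AG = str.maketrans("A", "G")
_COLLAPSE_TC = str.maketrans("T", "C")
_VALID = set("ACGTUN")


class InputError(ValueError):
    pass


def collapse_sequence(seq: str, mode: str) -> str:
    """Collapse a sequence for conversion-blind comparison.

    ``read`` and ``reference_plus`` map A->G (the sense-strand readout);
    ``reference_minus`` maps T->C (the same readout seen from the antisense
    reference strand). Length is preserved; U is normalised to T first.
    """
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= _VALID:
        raise InputError(f"invalid characters in sequence: {set(seq) - _VALID}")
    if mode in ("read", "reference_plus"):
        return seq.translate(_COLLAPSE_AG)
    if mode == "reference_minus":
        return seq.translate(_COLLAPSE_TC)
    raise InputError(f"unknown collapse mode {mode!r}")


def reverse_complement(seq: str) -> str:
    return seq.translate(DNA_COMP)[::-1]


@dataclass
class CollapsedIndex:
    """Seed table over both collapsed strands of a reference set."""

    references: dict[str, str]
    k: int
    seeds: dict[str, list[tuple[str, int, str]]] = field(repr=False, default=None)
    #: collapsed sequences, plus strand (A->G applied to forward reference)
    collapsed_plus: dict[str, str] = field(repr=False, default=None)
    #: collapsed reverse complement (sense space of minus-strand reads)
    collapsed_minus: dict[str, str] = field(repr=False, default=None)


def build_index(references: dict[str, str], k: int = 16) -> CollapsedIndex:
    """Index every collapsed k-mer of both strands.

    Minus-strand positions are stored in forward-reference coordinates of
    the k-mer start (leftmost base on the forward strand).
    """
    if k < 8:
        raise InputError("seed length k must be >= 8")
    if not references:
        raise InputError("empty reference")
    references = {
        name: seq.upper().replace("U", "T") for name, seq in references.items()
    }
    shortest = min(len(s) for s in references.values())
    if k > shortest:
        raise InputError(
            f"k={k} exceeds shortest reference length {shortest}"
        )
    seeds: dict[str, list[tuple[str, int, str]]] = {}
    plus: dict[str, str] = {}
    minus: dict[str, str] = {}
    for name, seq in references.items():
        cp = collapse_sequence(seq, "reference_plus")
        cm = collapse_sequence(reverse_complement(seq), "reference_plus")
        plus[name] = cp
        minus[name] = cm
        n = len(seq)
        for i in range(n - k + 1):
            seeds.setdefault(cp[i: i + k], []).append((name, i, "+"))
        for i in range(n - k + 1):
            # position of this k-mer's leftmost base on the forward strand
            seeds.setdefault(cm[i: i + k], []).append((name, n - k - i, "-"))
    return CollapsedIndex(
        references=references,
        k=k,
        seeds=seeds,
        collapsed_plus=plus,
        collapsed_minus=minus,
    )


@dataclass
class AlignmentRecord:
    read_id: str
    reference_id: str
    start: int  # 0-based on the forward reference strand
    strand: str
    mismatches: int
    unique: bool
    sequence: str = ""  # read bases, sequencing orientation (DNA)
    quality: str = ""


def _mismatches(a: str, b: str, cap: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > cap:
                return m
    return m


def align_read(
    read_id: str,
    sequence: str,
    index: CollapsedIndex,
    max_mismatch: Optional[int] = None,
    n_seeds: int = 3,
    quality: str = "",
) -> Optional[AlignmentRecord]:
    """Seed-and-extend ungapped alignment in collapsed space.

    The best location by fewest collapsed-space mismatches wins; an exact
    tie across locations is kept but flagged ``unique=False`` so downstream
    stages can discard it. Returns None when unmapped.
    """
    seq = sequence.upper().replace("U", "T")
    L = len(seq)
    if L < index.k:
        raise InputError(f"read {read_id} shorter than seed length {index.k}")
    if seq.count("N") > 0.1 * L:
        return None
    if max_mismatch is None:
        max_mismatch = max(1, int(0.05 * L))

    collapsed = collapse_sequence(seq, "read")
    k = index.k
    offsets = sorted({0, (L - k) // 2, L - k})[:n_seeds]

    candidates: set[tuple[str, int, str]] = set()
    for off in offsets:
        for name, pos, strand in index.seeds.get(
            collapsed[off: off + k], ()
        ):
            if strand == "+":
                start = pos - off
            else:
                # seed occupies forward [pos, pos+k); read offset `off` sits
                # at rc position (n-start-L)+off, hence:
                start = pos + k + off - L
            if start < 0:
                continue
            if start + L > len(index.references[name]):
                continue
            candidates.add((name, start, strand))

    best: list[tuple[str, int, str]] = []
    best_mm = max_mismatch + 1
    for name, start, strand in candidates:
        if strand == "+":
            ref = index.collapsed_plus[name][start: start + L]
        else:
            n = len(index.references[name])
            # sense-space segment of the minus strand covering forward
            # [start, start+L): positions n-start-L .. n-start on the rc
            ref = index.collapsed_minus[name][n - start - L: n - start]
        mm = _mismatches(collapsed, ref, best_mm)
        if mm < best_mm:
            best_mm = mm
            best = [(name, start, strand)]
        elif mm == best_mm and mm <= max_mismatch:
            best.append((name, start, strand))
    if not best or best_mm > max_mismatch:
        return None
    name, start, strand = best[0]
    return AlignmentRecord(
        read_id=read_id,
        reference_id=name,
        start=start,
        strand=strand,
        mismatches=best_mm,
        unique=len(best) == 1,
        sequence=seq,
        quality=quality or "I" * L,
    )


def align_reads(
    reads: Iterable[tuple[str, str, str]],
    index: CollapsedIndex,
    max_mismatch: Optional[int] = None,
) -> list[AlignmentRecord]:
    """Align (name, sequence, quality) triples; drops unmapped reads."""
    out = []
    for name, seq, qual in reads:
        if len(seq) < index.k:
            continue
        rec = align_read(name, seq, index, max_mismatch, quality=qual)
        if rec is not None:
            out.append(rec)
    return out


@dataclass
class SiteCount:
    """Stranded per-A-site tally of unconverted (A) vs converted (G) reads.

    ``context`` is the 21-nt window (-10..+10) around the site in transcript
    sense orientation, RNA alphabet, N-padded at reference edges. Coverage
    ``N = n_A + n_G`` counts informative bases only.
    """

    reference_id: str
    position: int
    strand: str
    context: str
    n_A: int
    n_G: int
    n_other: int

    def __post_init__(self) -> None:
        if self.context[len(self.context) // 2] != "A":
            raise ValueError("central context base must be A (sense strand)")
        if min(self.n_A, self.n_G, self.n_other) < 0:
            raise ValueError("negative counts")

    @property
    def coverage(self) -> int:
        return self.n_A + self.n_G

    def central_motif(self, length: int = 3) -> str:
        mid = len(self.context) // 2
        flank = length // 2
        return self.context[mid - flank: mid + flank + 1]


_BASE_TO_IDX = {b: i for i, b in enumerate("ACGTN")}


def pileup_A_sites(
    alignments: Iterable[AlignmentRecord],
    references: dict[str, str],
    min_base_quality: int = 20,
    min_coverage: int = 20,
) -> list[SiteCount]:
    """Count A/G evidence at every sense-strand A of the reference.

    Only unique alignments contribute. Sites are emitted when coverage
    strictly exceeds ``min_coverage``. For minus-strand sites (forward-
    reference T) read bases are complemented into sense space.
    """
    references = {
        name: seq.upper().replace("U", "T") for name, seq in references.items()
    }
    mats: dict[str, dict[str, np.ndarray]] = {}
    for name, seq in references.items():
        mats[name] = {
            "+": np.zeros((5, len(seq)), dtype=np.int64),
            "-": np.zeros((5, len(seq)), dtype=np.int64),
        }

    for aln in alignments:
        if not aln.unique:
            continue
        ref = references.get(aln.reference_id)
        if ref is None:
            raise InputError(f"alignment to unknown reference {aln.reference_id}")
        L = len(aln.sequence)
        if aln.start < 0 or aln.start + L > len(ref):
            raise InputError("alignment extends past reference end")
        if aln.strand == "+":
            bases = aln.sequence
            quals = aln.quality
            start = aln.start
        else:
            bases = reverse_complement(aln.sequence)
            quals = aln.quality[::-1]
            start = aln.start
        idx = np.fromiter(
            (_BASE_TO_IDX.get(b, 4) for b in bases), dtype=np.int64, count=L
        )
        q = np.frombuffer(quals.encode(), dtype=np.uint8) - 33
        keep = q >= min_base_quality
        pos = np.arange(start, start + L)[keep]
        np.add.at(mats[aln.reference_id][aln.strand], (idx[keep], pos), 1)

    sites: list[SiteCount] = []
    for name, seq in references.items():
        plus = mats[name]["+"]
        minus = mats[name]["-"]
        for pos, base in enumerate(seq):
            if base == "A":
                col = plus[:, pos]
                n_a, n_g = int(col[0]), int(col[2])
                n_other = int(col[1] + col[3])
                strand = "+"
                ctx = _window(seq, pos, 10)
            elif base == "T":
                col = minus[:, pos]
                # sense A reads as forward T; sense G as forward C
                n_a, n_g = int(col[3]), int(col[1])
                n_other = int(col[0] + col[2])
                strand = "-"
                ctx = reverse_complement(_window(seq, pos, 10))
            else:
                continue
            if n_a + n_g <= min_coverage:
                continue
            sites.append(
                SiteCount(
                    reference_id=name,
                    position=pos,
                    strand=strand,
                    context=ctx.replace("T", "U"),
                    n_A=n_a,
                    n_G=n_g,
                    n_other=n_other,
                )
            )
    sites.sort(key=lambda s: (s.reference_id, s.position))
    return sites


def _window(seq: str, pos: int, flank: int) -> str:
    left = seq[max(0, pos - flank): pos]
    right = seq[pos + 1: pos + 1 + flank]
    return (
        "N" * (flank - len(left)) + left + seq[pos] + right
        + "N" * (flank - len(right))
    )


def brute_force_align(
    sequence: str, references: dict[str, str], max_mismatch: int
) -> Optional[AlignmentRecord]:
    """All-positions scorer used as the aligner's oracle on small references.

    Scores every start on both strands in collapsed space and applies the
    same best/tie rule as :func:`align_read`. Quadratic; test use only.
    """
    seq = sequence.upper().replace("U", "T")
    collapsed = collapse_sequence(seq, "read")
    L = len(seq)
    best: list[tuple[str, int, str]] = []
    best_mm = max_mismatch + 1
    for name, ref in references.items():
        ref = ref.upper().replace("U", "T")
        cp = collapse_sequence(ref, "reference_plus")
        cm = collapse_sequence(reverse_complement(ref), "reference_plus")
        n = len(ref)
        for start in range(n - L + 1):
            mm = _mismatches(collapsed, cp[start: start + L], best_mm)
            if mm < best_mm:
                best_mm, best = mm, [(name, start, "+")]
            elif mm == best_mm and mm <= max_mismatch:
                best.append((name, start, "+"))
            mm = _mismatches(
                collapsed, cm[n - start - L: n - start], best_mm
            )
            if mm < best_mm:
                best_mm, best = mm, [(name, start, "-")]
            elif mm == best_mm and mm <= max_mismatch:
                best.append((name, start, "-"))
    if not best or best_mm > max_mismatch:
        return None
    name, start, strand = best[0]
    return AlignmentRecord(
        read_id="", reference_id=name, start=start, strand=strand,
        mismatches=best_mm, unique=len(best) == 1, sequence=seq,
    )
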