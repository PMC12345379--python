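"""File formats: FASTA/FASTQ via Biopython, SAM via pysam (minimal dialect),
BED/TSV/GTF as plain text tables."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentRecord, SiteCount
from .calling import SiteCall
from .simulate import GroundTruthSite, SimulatedRead, TranscriptModel


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(transcripts: Sequence[TranscriptModel], path) -> None:
    records = [
        SeqRecord(
            Seq(t.sequence.replace("U", "T")), id=t.id, description=""
        )
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fastq(reads: Sequence[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Return (name, sequence, quality) triples; line-numbered parse errors."""
    triples = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ParseError(
            f"truncated FASTQ record at line {len(lines) - len(lines) % 4 + 1}"
        )
    for i in range(0, len(lines), 4):
        if not lines[i].startswith("@"):
            raise ParseError(f"expected @ header at line {i + 1}")
        if not lines[i + 2].startswith("+"):
            raise ParseError(f"expected + separator at line {i + 3}")
        if len(lines[i + 1]) != len(lines[i + 3]):
            raise ParseError(f"sequence/quality length mismatch at line {i + 2}")
        triples.append((lines[i][1:].split()[0], lines[i + 1], lines[i + 3]))
    return triples


# ------------------------------------------------------------------------ BED

def write_truth_bed(truth: Sequence[GroundTruthSite], path) -> None:
    """BED6+2: chrom, start, end, name, score placeholder, strand, level, motif5."""
    with open(path, "w") as fh:
        for s in truth:
            fh.write(
                f"{s.transcript_id}\t{s.position}\t{s.position + 1}\t"
                f"{s.motif3}\t0\t+\t{s.true_level:.6f}\t{s.motif5}\n"
            )


def read_truth_bed(path) -> list[GroundTruthSite]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ParseError(f"BED line {lineno}: expected 8 fields")
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise ParseError(f"BED line {lineno}: end <= start")
            out.append(
                GroundTruthSite(
                    transcript_id=f[0], position=start,
                    true_level=float(f[6]), motif3=f[3], motif5=f[7],
                )
            )
    return out


def write_calls_bed(calls: Sequence[SiteCall], path) -> None:
    """BED6+3 export: name=motif5, score=round(1000*level)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.reference_id}\t{c.position}\t{c.position + 1}\t"
                f"{c.central_motif(5)}\t{round(1000 * c.level)}\t{c.strand}\t"
                f"{c.level:.6f}\t{c.p_value:.6g}\t{int(c.significant)}\n"
            )


# ------------------------------------------------------------------------ GTF

def write_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    """Minimal GTF: one transcript and one CDS feature per transcript."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.id}"; transcript_id "{t.id}";'
            fh.write(
                f"{t.id}\tcamseq\ttranscript\t1\t{len(t.sequence)}\t.\t+\t.\t"
                f"{attrs}\n"
            )
            fh.write(
                f"{t.id}\tcamseq\tCDS\t{t.cds_start + 1}\t{t.cds_end}\t.\t+\t"
                f".\t{attrs}\n"
            )


def read_gtf(path, sequences: dict[str, str]) -> dict[str, TranscriptModel]:
    """Rebuild TranscriptModels from a minimal GTF plus their sequences."""
    cds: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ParseError(f"GTF line {lineno}: expected 9 fields")
            if f[2] != "CDS":
                continue
            cds[f[0]] = (int(f[3]) - 1, int(f[4]))
    out = {}
    for name, seq in sequences.items():
        start, end = cds.get(name, (0, len(seq)))
        out[name] = TranscriptModel(
            id=name, sequence=seq.replace("T", "U"), cds_start=start,
            cds_end=end, expression_weight=1.0,
        )
    return out


# ------------------------------------------------------------------------ SAM

def write_sam(
    alignments: Sequence[AlignmentRecord],
    references: dict[str, str],
    path,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": len(seq)} for name, seq in references.items()
        ],
    }
    names = list(references)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.reference_id = names.index(a.reference_id)
            seg.reference_start = a.start
            seg.flag = 16 if a.strand == "-" else 0
            if not a.unique:
                seg.flag |= 0x100
            seq = a.sequence
            qual = a.quality or "I" * len(seq)
            if a.strand == "-":
                seq = str(Seq(seq).reverse_complement())
                qual = qual[::-1]
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array(qual)
            seg.cigarstring = f"{len(seq)}M"
            seg.mapping_quality = 60 if a.unique else 0
            seg.set_tag("NM", a.mismatches)
            fh.write(seg)


def read_sam(path) -> list[AlignmentRecord]:
    """Parse the minimal SAM dialect back into alignment records.

    SEQ/QUAL are restored to sequencing orientation from the FLAG strand
    bit, matching what the aligner produced.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            seq = seg.query_sequence or ""
            qual = pysam.qualities_to_qualitystring(seg.query_qualities or [])
            strand = "-" if seg.is_reverse else "+"
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
                qual = qual[::-1]
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    reference_id=seg.reference_name,
                    start=seg.reference_start,
                    strand=strand,
                    mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    unique=not (seg.flag & 0x100),
                    sequence=seq,
                    quality=qual,
                )
            )
    return out


# ------------------------------------------------------------------------ TSV

SITE_COLUMNS = ["ref", "pos0", "strand", "context21", "n_A", "n_G", "n_other"]
CALL_COLUMNS = SITE_COLUMNS + [
    "level", "p_value", "significant", "passes_level_5", "passes_level_10",
]


def write_site_counts(sites: Sequence[SiteCount], path) -> None:
    pd.DataFrame(
        [
            (s.reference_id, s.position, s.strand, s.context, s.n_A, s.n_G,
             s.n_other)
            for s in sites
        ],
        columns=SITE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_site_counts(path) -> list[SiteCount]:
    df = pd.read_csv(path, sep="\t", dtype={"context21": str})
    return [
        SiteCount(
            reference_id=str(r.ref), position=int(r.pos0), strand=str(r.strand),
            context=str(r.context21), n_A=int(r.n_A), n_G=int(r.n_G),
            n_other=int(r.n_other),
        )
        for r in df.itertuples()
    ]


def write_calls(calls: Sequence[SiteCall], path) -> None:
    pd.DataFrame(
        [
            (c.reference_id, c.position, c.strand, c.context, c.n_A, c.n_G,
             c.n_other, c.level, c.p_value, c.significant, c.passes_level_5,
             c.passes_level_10)
            for c in calls
        ],
        columns=CALL_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[SiteCall]:
    df = pd.read_csv(path, sep="\t", dtype={"context21": str})
    return [
        SiteCall(
            reference_id=str(r.ref), position=int(r.pos0), strand=str(r.strand),
            context=str(r.context21), n_A=int(r.n_A), n_G=int(r.n_G),
            n_other=int(r.n_other), level=float(r.level),
            p_value=float(r.p_value), significant=bool(r.significant),
            passes_level_5=bool(r.passes_level_5),
            passes_level_10=bool(r.passes_level_10),
        )
        for r in df.itertuples()
    ]


# ------------------------------------------------------------------ roundtrip

def validate_roundtrip(path, fmt: str) -> bool:
    """read -> write -> read must reproduce identical records."""
    path = Path(path)
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        tmp_path = Path(tmp) / path.name
        if fmt == "fastq":
            first = read_fastq(path)
            with open(tmp_path, "w") as fh:
                for name, seq, qual in first:
                    fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            again = read_fastq(tmp_path)
        elif fmt == "fasta":
            first = read_fasta(path)
            SeqIO.write(
                [
                    SeqRecord(Seq(s), id=n, description="")
                    for n, s in first.items()
                ],
                str(tmp_path), "fasta",
            )
            again = read_fasta(tmp_path)
        elif fmt == "bed":
            first = read_truth_bed(path)
            write_truth_bed(first, tmp_path)
            again = read_truth_bed(tmp_path)
        elif fmt == "sam":
            first = read_sam(path)
            refs = _sam_references(path)
            write_sam(first, refs, tmp_path)
            again = read_sam(tmp_path)
        elif fmt == "tsv":
            first = read_site_counts(path)
            write_site_counts(first, tmp_path)
            again = read_site_counts(tmp_path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    if isinstance(first, list) and first and dataclasses.is_dataclass(first[0]):
        same = all(a == b for a, b in zip(first, again)) and len(first) == len(again)
    else:
        same = first == again
    if not same:
        raise ParseError(f"{fmt} roundtrip mismatch for {path}")
    return True


def _sam_references(path) -> dict[str, str]:
    refs = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for sq in fh.header.get("SQ", []):
            refs[sq["SN"]] = "N" * sq["LN"]
    return refs
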