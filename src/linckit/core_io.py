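"""Core data model and format I/O.

All genomic coordinates are 0-based, half-open internally.  GTF/GFF files
(1-based, inclusive) are converted at the boundary; BED is native.  Strand is
one of ``+``, ``-`` or ``.`` where ``.`` is a first-class "unknown" value that
downstream classification rules consume explicitly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line/record."""


@dataclass
class SequenceRecord:
    """A named DNA sequence.

    Sequences are stored uppercase.  Pipe characters in ids are stripped on
    read (genome FASTA headers are often prefixed ``lcl|``/``gi|`` while the
    matching annotation is not).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a sequence, optionally stranded."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A (possibly multi-exon) transcript with a genomic span.

    Exons are kept sorted by start, must be pairwise disjoint, and lie on the
    same seq_id/strand; the span is derived from the first/last exon.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        seq_ids = {e.seq_id for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seq_ids) > 1 or len(strands) > 1:
            raise ParseError(
                f"transcript {self.transcript_id}: exons disagree on "
                f"seq_id/strand ({seq_ids}, {strands})"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """Concatenate exon sequences; reverse-complemented for '-' strand."""
        chrom = genome.get(self.seq_id)
        if chrom is None:
            raise KeyError(
                f"transcript {self.transcript_id} references absent "
                f"chromosome {self.seq_id}"
            )
        s = "".join(chrom[e.start : e.end] for e in self.exons)
        return revcomp(s) if self.strand == "-" else s

    def with_strand(self, strand: str) -> "TranscriptModel":
        exons = [replace(e, strand=strand) for e in self.exons]
        return TranscriptModel(self.transcript_id, self.gene_id, exons)


class AnnotationSet:
    """A collection of transcripts with a per-chromosome interval index.

    The index answers span-overlap queries exactly (verified against brute
    force in the test suite).
    """

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self.transcripts: dict[str, TranscriptModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        sp = t.span
        self._trees.setdefault(sp.seq_id, IntervalTree()).addi(
            sp.start, sp.end, t.transcript_id
        )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def overlapping(self, probe: GenomicInterval) -> list[TranscriptModel]:
        """Transcripts whose genomic span overlaps *probe* (strand-blind)."""
        tree = self._trees.get(probe.seq_id)
        if tree is None:
            return []
        ids = sorted(iv.data for iv in tree.overlap(probe.start, probe.end))
        return [self.transcripts[i] for i in ids]


@dataclass
class Config:
    """Every numeric threshold of the pipeline, single source of truth.

    Defaults are the published operating points: transcripts must exceed
    200 nt; ORFs above 100 aa or a protein hit at E <= 1e-5 mark a transcript
    coding; TE similarity at bit score >= 200 and E <= 1e-20 marks it
    TE-derived; a TSS within 100 bp of the 5' end flags CAGE support; 500 bp
    flanks approximate missing UTR annotation; homology searches run at
    E <= 1e-20 with a 200-nt segmentation fallback; bootstrap 70 gates
    gene-tree rearrangement during reconciliation.
    """

    min_transcript_len: int = 200
    max_noncoding_orf_aa: int = 100
    protein_evalue: float = 1e-5
    te_bitscore: float = 200.0
    te_evalue: float = 1e-20
    tss_window: int = 100
    flank_extension: int = 500
    search_evalue: float = 1e-20
    segment_len: int = 200
    min_segment_len: int = 100
    merge_gap: int = 10_000
    bootstrap_threshold: float = 70.0
    # built-in aligner scoring (classic nucleotide-search defaults)
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 11
    # reciprocity: minimum overlap fraction of the query locus (0 = any >=1 bp)
    reciprocal_min_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_transcript_len", "max_noncoding_orf_aa", "protein_evalue",
            "te_bitscore", "te_evalue", "tss_window", "search_evalue",
            "segment_len", "min_segment_len", "merge_gap",
            "bootstrap_threshold", "match", "gap_open", "gap_extend",
            "word_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"Config.{name} must be strictly positive")
        if self.mismatch >= 0:
            raise ValueError("Config.mismatch must be negative")
        if self.flank_extension < 0:
            raise ValueError("Config.flank_extension must be >= 0")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, clean_pipes: bool = True) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    The id is the header token before the first whitespace; the rest is the
    description.  Pipe characters are stripped from ids (with a logged
    warning) unless ``clean_pipes`` is false.  Duplicate ids and headerless
    content are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first and first not in (">", "\n", "\r"):
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if clean_pipes and "|" in rid:
            cleaned = rid.replace("|", "")
            log.warning("stripped pipe characters from FASTA id %r -> %r", rid, cleaned)
            rid = cleaned
        if rid in seen:
            raise ParseError(f"{path}: duplicate FASTA id {rid!r}")
        seen.add(rid)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rid, str(rec.seq), desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GTF / GFF

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]*)")


def _parse_attributes(text: str) -> dict[str, str]:
    """Parse attribute column in either GTF or GFF3 dialect."""
    text = text.strip()
    if "=" in text.split(";")[0] and '"' not in text.split(";")[0]:
        return {k: v for k, v in _GFF3_ATTR.findall(text)}
    return {k: v for k, v in _GTF_ATTR.findall(text)}


def _iter_feature_lines(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}: line {lineno}: expected >=8 tab-separated fields")
            yield lineno, fields


def read_transcript_gtf(path: str | Path) -> AnnotationSet:
    """Read an assembled-transcript GTF (Cuffmerge/StringTie style).

    Exon features are grouped by ``transcript_id`` into TranscriptModels;
    1-based inclusive coordinates become 0-based half-open.  Any line
    providing a transcript_id is accepted regardless of attribute dialect.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    order: list[str] = []
    for lineno, f in _iter_feature_lines(path):
        if f[2] != "exon":
            continue
        attrs = _parse_attributes(f[8]) if len(f) > 8 else {}
        tid = attrs.get("transcript_id")
        if not tid:
            raise ParseError(f"{path}: line {lineno}: exon without transcript_id")
        strand = f[6] if f[6] in ("+", "-") else "."
        iv = GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), strand)
        exons.setdefault(tid, []).append(iv)
        gene_of.setdefault(tid, attrs.get("gene_id", tid))
        if tid not in order:
            order.append(tid)
    annot = AnnotationSet()
    for tid in order:
        annot.add(TranscriptModel(tid, gene_of[tid], exons[tid]))
    return annot


def read_annotation_gff(path: str | Path, feature_types: Sequence[str] | None = None) -> AnnotationSet:
    """Read a reference annotation (GFF3 or GTF) as single-span gene models.

    By default ``gene`` features are used; if none are present, ``mRNA`` /
    ``transcript`` features are used instead, so sparse annotations still
    load.  Each feature becomes a single-exon TranscriptModel keyed by its
    ID/gene_id attribute (or an autogenerated key).
    """
    path = Path(path)
    preferred = feature_types or ("gene",)
    fallback = ("mRNA", "transcript")
    rows: dict[str, list[tuple[str, GenomicInterval, str]]] = {t: [] for t in (*preferred, *fallback)}
    for lineno, f in _iter_feature_lines(path):
        ftype = f[2]
        if ftype not in rows:
            continue
        attrs = _parse_attributes(f[8]) if len(f) > 8 else {}
        fid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("transcript_id") or f"feat{lineno}"
        strand = f[6] if f[6] in ("+", "-") else "."
        iv = GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), strand)
        rows[ftype].append((fid, iv, attrs.get("Name", "")))
    chosen = next((t for t in preferred if rows[t]), None)
    if chosen is None:
        chosen = next((t for t in fallback if rows[t]), preferred[0])
    annot = AnnotationSet()
    for fid, iv, _name in rows[chosen]:
        if fid in annot.transcripts:  # isoform lines sharing an ID: keep widest span
            old = annot.transcripts[fid].span
            if iv.start >= old.start and iv.end <= old.end:
                continue
            fid = f"{fid}.{len(annot)}"
        annot.add(TranscriptModel(fid, fid, [iv]))
    return annot


def extend_gene_coordinates(
    annot: AnnotationSet, flank: int, chrom_sizes: dict[str, int]
) -> AnnotationSet:
    """Widen every gene span by *flank* nt on both sides, clamped to the chromosome.

    Approximates missing UTR annotation so that transcripts abutting gene ends
    are not called intergenic.  Exon structure inside the span is collapsed to
    the widened span (only spans are consulted for overlap classification).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = AnnotationSet()
    for t in annot:
        size = chrom_sizes.get(t.seq_id)
        start = max(0, t.span.start - flank)
        end = t.span.end + flank
        if size is not None:
            end = min(size, end)
        out.add(
            TranscriptModel(
                t.transcript_id,
                t.gene_id,
                [GenomicInterval(t.seq_id, start, end, t.strand)],
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED / GFF writers

def write_bed(
    entries: Iterable[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    """Write (interval, name) pairs as BED6; score column is '.'."""
    with open(path, "w") as fh:
        for iv, name in entries:
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t.\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}: line {lineno}: BED needs >=3 columns")
            name = f[3] if len(f) > 3 else f"bed{lineno}"
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append((GenomicInterval(f[0], int(f[1]), int(f[2]), strand), name))
    return out


def write_gff(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "linckit",
    feature_type: str = "gene",
    append: bool = False,
) -> None:
    """Write transcripts as GFF3 (1-based inclusive); one feature per span
    plus exon child lines for multi-exon models."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("##gff-version 3\n")
        for t in transcripts:
            sp = t.span
            strand = sp.strand if sp.strand in ("+", "-") else "."
            fh.write(
                f"{sp.seq_id}\t{source}\t{feature_type}\t{sp.start + 1}\t{sp.end}\t.\t"
                f"{strand}\t.\tID={t.transcript_id};gene_id={t.gene_id}\n"
            )
            if len(t.exons) > 1 or feature_type != "gene":
                for i, e in enumerate(t.exons, 1):
                    fh.write(
                        f"{e.seq_id}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{strand}\t.\tID={t.transcript_id}.exon{i};"
                        f"Parent={t.transcript_id}\n"
                    )


def write_transcript_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as a GTF of exon features (round-trips with
    read_transcript_gtf)."""
    with open(path, "w") as fh:
        for t in transcripts:
            strand = t.strand if t.strand in ("+", "-") else "."
            for e in t.exons:
                fh.write(
                    f"{e.seq_id}\tlinckit\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t"
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";\n'
                )


# ---------------------------------------------------------------------------
# transcript-coordinate projection

def project_to_genome(
    exons: Sequence[GenomicInterval], strand: str, t_start: int, t_end: int
) -> list[GenomicInterval]:
    """Project a transcript-coordinate interval [t_start, t_end) through an
    exon map to genomic blocks (one per exon crossed).

    Transcript coordinate 0 is the 5' end: the first exon start for '+', the
    last exon end for '-'.  Unknown strand is treated as '+'.
    """
    if t_start < 0 or t_end <= t_start:
        raise ValueError("invalid transcript interval")
    ordered = list(exons) if strand != "-" else list(reversed(exons))
    blocks: list[GenomicInterval] = []
    off = 0
    for e in ordered:
        lo = max(t_start, off)
        hi = min(t_end, off + e.length)
        if lo < hi:
            if strand == "-":
                blocks.append(
                    GenomicInterval(e.seq_id, e.end - (hi - off), e.end - (lo - off), strand)
                )
            else:
                blocks.append(
                    GenomicInterval(e.seq_id, e.start + (lo - off), e.start + (hi - off), e.strand)
                )
        off += e.length
    return sorted(blocks, key=lambda b: b.start)
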