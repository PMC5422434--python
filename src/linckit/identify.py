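"""lincRNA identification from assembled transcripts.

Partitions every input transcript into exactly one class:

* ``REJECTED_SHORT``   — spliced length not greater than 200 nt
* ``REJECTED_CODING``  — ORF > 100 aa, or a protein-database hit at E <= 1e-5
* ``TE_DERIVED``       — transposable-element similarity at bit >= 200 and E <= 1e-20
* ``SOT`` / ``AOT``    — overlaps an annotated gene on the same / opposite strand
* ``AMBIGUOUS_OVERLAP``— overlaps a gene but the strand cannot be inferred
* ``LINCRNA``          — everything that survives: intergenic, long, non-coding

Strand inference for overlap classification needs either an explicit strand
(stranded RNA-seq assemblies carry one) or a multi-exonic structure, in which
case splice-site orientation (GT..AG) recovers it from the genome.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core_io import (
    AnnotationSet,
    Config,
    GenomicInterval,
    SequenceRecord,
    TranscriptModel,
    extend_gene_coordinates,
    read_annotation_gff,
    read_bed,
    read_fasta,
    read_transcript_gtf,
    write_bed,
    write_fasta,
    write_gff,
)
from .search import BuiltinSearchEngine, merge_hits, select_tbh

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
KNOWN_LNC_SUFFIX = "_overlapping_known_lncRNA"


class LncClass(enum.Enum):
    LINCRNA = "lincRNA"
    SOT = "SOT"
    AOT = "AOT"
    TE_DERIVED = "TE_derived"
    AMBIGUOUS_OVERLAP = "ambiguous_overlap"
    REJECTED_SHORT = "rejected_short"
    REJECTED_CODING = "rejected_coding"


@dataclass
class CodingAssessment:
    transcript_id: str
    longest_orf_aa: int
    best_hit_evalue: float | None
    verdict: str  # "coding" | "noncoding"

    @property
    def has_protein_hit(self) -> bool:
        return self.best_hit_evalue is not None


@dataclass
class LincRNARecord:
    model: TranscriptModel
    seq: str
    lnc_class: LncClass
    cage_plus: bool = False
    known_lincRNA_id: str | None = None
    known_lincRNA_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def exon_count(self) -> int:
        return self.model.exon_count

    @property
    def output_id(self) -> str:
        rid = self.model.transcript_id
        if self.known_lincRNA_id is not None:
            rid += KNOWN_LNC_SUFFIX
        return rid

    def to_sequence_record(self) -> SequenceRecord:
        desc = "CAGE_PLUS" if self.cage_plus else ""
        return SequenceRecord(self.output_id, self.seq, desc)


# ---------------------------------------------------------------------------
# filters

def filter_by_length(
    records: list[LincRNARecord], min_len: int
) -> tuple[list[LincRNARecord], list[LincRNARecord]]:
    """Keep transcripts whose spliced length strictly exceeds *min_len*."""
    kept = [r for r in records if r.length > min_len]
    rejected = [r for r in records if r.length <= min_len]
    return kept, rejected


def find_longest_orf(seq: str) -> int:
    """Length in amino acids (stop excluded) of the longest complete ORF over
    all six reading frames; 0 when no ATG-initiated, stop-terminated ORF
    exists."""
    from .core_io import revcomp

    best = 0
    for s in (seq.upper(), revcomp(seq.upper())):
        for frame in range(3):
            start = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        best = max(best, (i - start) // 3)
                        start = None
                elif start is None and codon == "ATG":
                    start = i
    return best


def assess_coding(
    record: LincRNARecord,
    protein_hits: list[float] | None,
    cfg: Config,
) -> CodingAssessment:
    """Two-metric coding call: a long ORF or a significant protein hit.

    *protein_hits* is a possibly-empty list of E-values from a protein
    similarity search (pluggable: an external BLASTp adapter or a
    user-supplied hit table).
    """
    orf = find_longest_orf(record.seq)
    best = min(protein_hits) if protein_hits else None
    coding = orf > cfg.max_noncoding_orf_aa or (
        best is not None and best <= cfg.protein_evalue
    )
    return CodingAssessment(
        record.model.transcript_id, orf, best, "coding" if coding else "noncoding"
    )


def filter_te(
    records: list[LincRNARecord],
    te_hits: dict[str, tuple[float, float]] | None,
    cfg: Config,
) -> tuple[list[LincRNARecord], list[LincRNARecord]]:
    """Split off TE-derived transcripts.

    *te_hits* maps transcript_id to its best (bitscore, evalue) against the
    TE database; None means no database was supplied and the step is a
    no-op.  A transcript is TE-derived only when bitscore >= cfg.te_bitscore
    AND evalue <= cfg.te_evalue (both thresholds must be exceeded).
    """
    if te_hits is None:
        return [], list(records)
    te_derived, retained = [], []
    for r in records:
        hit = te_hits.get(r.model.transcript_id)
        if hit is not None and hit[0] >= cfg.te_bitscore and hit[1] <= cfg.te_evalue:
            te_derived.append(r)
        else:
            retained.append(r)
    return te_derived, retained


def infer_strand_from_splice_sites(
    model: TranscriptModel, genome: dict[str, str]
) -> str:
    """Infer strand of a multi-exon transcript from intron dinucleotides.

    Canonical introns read GT..AG on the template strand; on the opposite
    strand they appear as CT..AC.  Returns '+', '-' or '.' when the evidence
    is absent or conflicting.
    """
    chrom = genome.get(model.seq_id)
    if chrom is None or model.exon_count < 2:
        return "."
    votes = {"+": 0, "-": 0}
    for a, b in zip(model.exons, model.exons[1:]):
        donor = chrom[a.end : a.end + 2]
        acceptor = chrom[b.start - 2 : b.start]
        if donor == "GT" and acceptor == "AG":
            votes["+"] += 1
        elif donor == "CT" and acceptor == "AC":
            votes["-"] += 1
    if votes["+"] and not votes["-"]:
        return "+"
    if votes["-"] and not votes["+"]:
        return "-"
    return "."


def classify_overlap(model: TranscriptModel, annot: AnnotationSet) -> LncClass:
    """Sense/antisense overlap classification against annotated gene spans.

    LINCRNA when the span overlaps no gene; otherwise SOT/AOT by strand
    agreement with the overlapped gene (largest overlap wins when several
    genes are hit), or AMBIGUOUS_OVERLAP when either strand is unknown.
    """
    overlapping = annot.overlapping(model.span)
    if not overlapping:
        return LncClass.LINCRNA
    if model.strand not in ("+", "-"):
        return LncClass.AMBIGUOUS_OVERLAP

    def ov_len(g: TranscriptModel) -> int:
        return min(g.span.end, model.span.end) - max(g.span.start, model.span.start)

    gene = max(overlapping, key=lambda g: (ov_len(g), g.transcript_id))
    if gene.strand not in ("+", "-"):
        return LncClass.AMBIGUOUS_OVERLAP
    return LncClass.SOT if gene.strand == model.strand else LncClass.AOT


def annotate_tss(
    records: list[LincRNARecord],
    tss: list[tuple[GenomicInterval, str]],
    cfg: Config,
) -> None:
    """Flag lincRNAs whose 5' end lies within cfg.tss_window bp (inclusive)
    of any transcription start site.  Unknown-strand records fall back to the
    span start with a warning."""
    points: dict[str, list[tuple[int, int]]] = {}
    for iv, _name in tss:
        points.setdefault(iv.seq_id, []).append((iv.start, iv.end))
    for r in records:
        sp = r.model.span
        if r.model.strand == "+":
            five = sp.start
        elif r.model.strand == "-":
            five = sp.end - 1
        else:
            log.warning(
                "transcript %s has unknown strand; TSS distance uses span start",
                r.model.transcript_id,
            )
            five = sp.start
        best = None
        for s, e in points.get(sp.seq_id, ()):
            d = 0 if s <= five < e else min(abs(five - s), abs(five - (e - 1)))
            best = d if best is None else min(best, d)
        r.cage_plus = best is not None and best <= cfg.tss_window


def reconcile_known_lincRNAs(
    records: list[LincRNARecord], known: AnnotationSet
) -> None:
    """Mark lincRNAs whose genomic span overlaps a previously curated lincRNA
    locus; the nearest-by-midpoint overlapping locus gives the recorded id,
    all overlapping ids are kept for the summary table."""
    for r in records:
        hits = known.overlapping(r.model.span)
        if not hits:
            continue
        mid = r.model.span.midpoint
        hits.sort(key=lambda t: (abs(t.span.midpoint - mid), t.transcript_id))
        r.known_lincRNA_id = hits[0].transcript_id
        r.known_lincRNA_ids = [t.transcript_id for t in hits]


def group_into_loci(records: list[LincRNARecord]) -> list[list[LincRNARecord]]:
    """Cluster isoforms into loci: transitive closure of transcripts on the
    same sequence with compatible strands (equal, or either unknown) whose
    exons overlap."""
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    def compatible(a: TranscriptModel, b: TranscriptModel) -> bool:
        if a.seq_id != b.seq_id:
            return False
        if a.strand in ("+", "-") and b.strand in ("+", "-") and a.strand != b.strand:
            return False
        return any(
            ea.start < eb.end and eb.start < ea.end
            for ea in a.exons
            for eb in b.exons
        )

    order = sorted(range(n), key=lambda i: (records[i].model.seq_id, records[i].model.span.start))
    for pos, i in enumerate(order):
        for j in order[pos + 1 :]:
            if records[j].model.seq_id != records[i].model.seq_id:
                break
            if records[j].model.span.start >= records[i].model.span.end:
                break
            if compatible(records[i].model, records[j].model):
                union(i, j)
    clusters: dict[int, list[LincRNARecord]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(records[i])
    return sorted(
        clusters.values(),
        key=lambda c: (c[0].model.seq_id, min(r.model.span.start for r in c)),
    )


def demographics(by_class: dict[LncClass, list[LincRNARecord]]) -> pd.DataFrame:
    """Per-class transcript/locus counts, GC percent and length statistics."""
    rows = []
    for cls in (LncClass.LINCRNA, LncClass.SOT, LncClass.AOT, LncClass.TE_DERIVED):
        recs = by_class.get(cls, [])
        if not recs:
            rows.append(
                dict(lnc_class=cls.value, transcripts=0, loci=0, gc_percent=0.0,
                     min_length=0, max_length=0, mean_length=0.0)
            )
            continue
        concat = "".join(r.seq for r in recs)
        gc = 100.0 * sum(concat.count(b) for b in "GC") / len(concat)
        lengths = [r.length for r in recs]
        rows.append(
            dict(
                lnc_class=cls.value,
                transcripts=len(recs),
                loci=len(group_into_loci(recs)),
                gc_percent=round(gc, 2),
                min_length=min(lengths),
                max_length=max(lengths),
                mean_length=round(sum(lengths) / len(lengths), 2),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class IdentifyResult:
    classes: dict[str, LncClass]
    by_class: dict[LncClass, list[LincRNARecord]]
    summary: pd.DataFrame
    demographics: pd.DataFrame

    @property
    def lincRNAs(self) -> list[LincRNARecord]:
        return self.by_class.get(LncClass.LINCRNA, [])


def run_identify(
    gtf: str | Path,
    genome_fasta: str | Path,
    annotation: str | Path,
    te_db: str | Path | None = None,
    tss_bed: str | Path | None = None,
    known_lincrna_gff: str | Path | None = None,
    protein_hits: dict[str, list[float]] | None = None,
    cfg: Config | None = None,
    out_dir: str | Path | None = None,
    flank: int | None = None,
) -> IdentifyResult:
    """Run the full identification pipeline.

    Filter order: length -> coding -> TE -> gene overlap -> TSS -> known
    lincRNAs.  When *out_dir* is given, writes lincRNAs.FASTA, per-class
    FASTA/BED, an updated annotation GFF (reference plus lincRNA loci),
    Final_summary_table.tsv and a demographics report.
    """
    cfg = cfg or Config()
    flank = cfg.flank_extension if flank is None else flank
    genome = {r.id: r.seq for r in read_fasta(genome_fasta)}
    transcripts = read_transcript_gtf(gtf)
    missing = sorted(
        t.transcript_id for t in transcripts if t.seq_id not in genome
    )
    if missing:
        raise ValueError(
            "transcripts reference absent chromosomes: " + ", ".join(missing)
        )
    annot = read_annotation_gff(annotation)
    chrom_sizes = {k: len(v) for k, v in genome.items()}
    if flank:
        annot = extend_gene_coordinates(annot, flank, chrom_sizes)

    # strand inference for unstranded multi-exon transcripts
    models = []
    for t in transcripts:
        if t.strand == "." and t.exon_count >= 2:
            inferred = infer_strand_from_splice_sites(t, genome)
            if inferred != ".":
                t = t.with_strand(inferred)
        models.append(t)

    records = [
        LincRNARecord(m, m.spliced_sequence(genome), LncClass.LINCRNA) for m in models
    ]
    classes: dict[str, LncClass] = {}

    kept, short = filter_by_length(records, cfg.min_transcript_len)
    for r in short:
        r.lnc_class = LncClass.REJECTED_SHORT

    noncoding, coding = [], []
    for r in kept:
        hits = (protein_hits or {}).get(r.model.transcript_id)
        if assess_coding(r, hits, cfg).verdict == "coding":
            r.lnc_class = LncClass.REJECTED_CODING
            coding.append(r)
        else:
            noncoding.append(r)

    te_hits = None
    if te_db is not None:
        te_hits = _te_similarity(noncoding, te_db, cfg)
    te_derived, retained = filter_te(noncoding, te_hits, cfg)
    for r in te_derived:
        r.lnc_class = LncClass.TE_DERIVED

    lincs: list[LincRNARecord] = []
    for r in retained:
        r.lnc_class = classify_overlap(r.model, annot)
        if r.lnc_class == LncClass.LINCRNA:
            lincs.append(r)

    if tss_bed is not None:
        annotate_tss(lincs, read_bed(tss_bed), cfg)
    if known_lincrna_gff is not None:
        reconcile_known_lincRNAs(lincs, read_annotation_gff(known_lincrna_gff))

    by_class: dict[LncClass, list[LincRNARecord]] = {}
    for r in records:
        classes[r.model.transcript_id] = r.lnc_class
        by_class.setdefault(r.lnc_class, []).append(r)

    summary = pd.DataFrame(
        [
            dict(
                lincRNA_id=r.output_id,
                length=r.length,
                exon_count=r.exon_count,
                tss_support="CAGE_PLUS" if r.cage_plus else "",
                overlapping_known_lincRNA=";".join(r.known_lincRNA_ids),
            )
            for r in lincs
        ],
        columns=[
            "lincRNA_id", "length", "exon_count", "tss_support",
            "overlapping_known_lincRNA",
        ],
    )
    demo = demographics(by_class)
    result = IdentifyResult(classes, by_class, summary, demo)
    if out_dir is not None:
        _write_outputs(result, annotation, Path(out_dir))
    return result


def _te_similarity(
    records: list[LincRNARecord], te_db: str | Path, cfg: Config
) -> dict[str, tuple[float, float]]:
    """Best (bitscore, evalue) per transcript against the TE database, via
    the built-in search engine with the TE thresholds as cutoff."""
    te_records = read_fasta(te_db)
    engine = BuiltinSearchEngine()
    out: dict[str, tuple[float, float]] = {}
    for r in records:
        q = SequenceRecord(r.model.transcript_id, r.seq)
        hits = engine.search([q], te_records, cfg, evalue_cutoff=cfg.te_evalue)
        if hits:
            best = max(hits, key=lambda h: h.bitscore)
            out[r.model.transcript_id] = (best.bitscore, best.evalue)
    return out


def _write_outputs(result: IdentifyResult, annotation: str | Path, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    named = {
        LncClass.LINCRNA: "lincRNAs",
        LncClass.SOT: "SOT.lncRNAs",
        LncClass.AOT: "AOT.lncRNAs",
        LncClass.TE_DERIVED: "TE.derived.lncRNAs",
    }
    for cls, stem in named.items():
        recs = result.by_class.get(cls, [])
        write_fasta([r.to_sequence_record() for r in recs], out_dir / f"{stem}.FASTA")
        write_bed(
            [(r.model.span, r.output_id) for r in recs], out_dir / f"{stem}.bed"
        )
    result.summary.to_csv(out_dir / "Final_summary_table.tsv", sep="\t", index=False)
    result.demographics.to_csv(out_dir / "demographics.tsv", sep="\t", index=False)
    # updated annotation: reference file plus lincRNA loci appended
    updated = out_dir / "updated_annotation.gff"
    with open(annotation) as src, open(updated, "w") as dst:
        dst.write(src.read().rstrip("\n") + "\n")
    write_gff(
        [r.model for r in result.lincRNAs], updated,
        source="linckit", feature_type="lincRNA", append=True,
    )
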