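"""Synthetic genomes, annotations and transcript assemblies with planted truth.

Two generators cover the two pipelines:

* :func:`make_identify_fixture` plants coding, short, TE-derived, gene-
  overlapping and intergenic transcripts in a random genome, with a truth
  table of intended classes — the same design as validating an identification
  workflow on transcripts whose class is known in advance.
* :func:`make_panel_fixture` evolves an ancestral genome along a ladder
  species tree (per-branch substitutions, single-event indels of geometric
  length) with planted lincRNA loci, optional losses on chosen species and
  duplications, so homolog recovery, conservation depth and duplication/loss
  reconciliation can all be checked against ground truth.

Everything is driven by one seeded generator: the same seed reproduces the
output byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    GenomicInterval,
    SequenceRecord,
    TranscriptModel,
    revcomp,
    write_bed,
    write_fasta,
    write_gff,
    write_transcript_gtf,
)
from .identify import find_longest_orf

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
# the 61 sense codons
_SENSE = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class FixtureSpec:
    """Knobs for both generators; defaults are the study conditions used
    throughout the test-suite.

    Rates are expected events per site and must lie in [0, 0.75); counts are
    non-negative.  ``fraction_shallow`` of the panel lincRNAs are deleted in
    every species deeper than ``shallow_depth`` (planting a conservation-depth
    signal).
    """

    seed: int = 0
    # identification fixture
    n_coding: int = 20
    n_coding_by_hit: int = 0     # non-coding ORF but significant protein hit
    n_lincrna: int = 10
    n_cage: int = 5              # of the lincRNAs, how many get a TSS at the 5' end
    n_known_overlap: int = 3     # of the lincRNAs, how many overlap a curated lincRNA
    n_te: int = 5
    n_te_families: int = 3
    n_sot: int = 5
    n_aot: int = 5
    n_short: int = 5
    n_ambiguous: int = 0
    spacer: int = 1500           # nt between planted blocks; exceeds the 500-nt flank
    te_mutation_rate: float = 0.02
    truncate_coding_aa: int | None = None  # plant ORFs of this size instead of >100 aa
    # panel fixture
    n_species: int = 5
    substitution_rate: float = 0.03
    indel_rate: float = 0.0005
    n_panel_queries: int = 20
    locus_length: int = 500
    panel_spacer: int = 1200
    fraction_shallow: float = 0.0
    shallow_depth: int = 2
    loss_species: dict[str, list[str]] = field(default_factory=dict)
    duplication_species: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "te_mutation_rate", "fraction_shallow"):
            v = getattr(self, name)
            if not (0.0 <= v < 0.75):
                raise ValueError(f"FixtureSpec.{name} must lie in [0, 0.75)")
        for name in (
            "n_coding", "n_coding_by_hit", "n_lincrna", "n_cage", "n_known_overlap",
            "n_te", "n_sot", "n_aot", "n_short", "n_ambiguous", "n_panel_queries",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"FixtureSpec.{name} must be >= 0")
        if self.n_species < 2:
            raise ValueError("panel needs at least 2 species")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, n))


def _noncoding_dna(rng: np.random.Generator, n: int, max_orf: int = 100) -> str:
    """Random DNA guaranteed to carry no complete ORF longer than *max_orf* aa."""
    while True:
        s = _rand_dna(rng, n)
        if find_longest_orf(s) <= max_orf:
            return s


def _coding_dna(rng: np.random.Generator, n_aa: int, utr: int = 50) -> str:
    """UTR + ATG + (n_aa-1) sense codons + stop + UTR: one complete ORF of
    exactly n_aa amino acids."""
    body = "ATG" + "".join(rng.choice(_SENSE, n_aa - 1)) + str(rng.choice(_STOPS))
    while True:
        left = _noncoding_dna(rng, utr, max_orf=20)
        right = _noncoding_dna(rng, utr, max_orf=20)
        s = left + body + right
        if find_longest_orf(s) == n_aa:
            return s


def _mutate_subs(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    for i in np.where(mask)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# identification fixture

@dataclass
class IdentifyFixture:
    out_dir: Path
    genome: Path
    transcripts_gtf: Path
    annotation_gff: Path
    te_db: Path | None
    tss_bed: Path
    known_lincrna_gff: Path | None
    truth: pd.DataFrame
    protein_hits: dict[str, list[float]]
    protein_hits_tsv: Path | None = None


def make_identify_fixture(spec: FixtureSpec, out_dir: str | Path) -> IdentifyFixture:
    """Generate genome, annotation, transcript GTF, TE database, TSS BED,
    known-lincRNA GFF and a truth table of planted classes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    te_families = [
        SequenceRecord(f"TEfam{i+1}", _noncoding_dna(rng, 500))
        for i in range(spec.n_te_families)
    ] if spec.n_te else []

    chrom = "Chr1"
    pieces: list[str] = []
    offset = 0
    transcripts: list[TranscriptModel] = []
    genes: list[TranscriptModel] = []
    known: list[TranscriptModel] = []
    tss: list[tuple[GenomicInterval, str]] = []
    truth_rows: list[dict] = []
    protein_hits: dict[str, list[float]] = {}

    def emit(block: str) -> int:
        nonlocal offset
        start = offset
        pieces.append(block)
        offset += len(block)
        pieces.append(_rand_dna(rng, spec.spacer))
        offset += spec.spacer
        return start

    def add_tx(tid: str, exons: list[GenomicInterval], cls: str, **extra) -> None:
        transcripts.append(TranscriptModel(tid, f"G.{tid}", exons))
        truth_rows.append(dict(transcript_id=tid, lnc_class=cls, **extra))

    # coding transcripts (not present in the annotation, like an FDR test set)
    for i in range(spec.n_coding):
        if spec.truncate_coding_aa is not None:
            n_aa = spec.truncate_coding_aa
            cls = "lincRNA"  # a sub-100-aa ORF passes the coding filter
        else:
            n_aa = int(rng.integers(101, 400))
            cls = "rejected_coding"
        block = _coding_dna(rng, n_aa)
        s = emit(block)
        add_tx(f"COD{i+1}", [GenomicInterval(chrom, s, s + len(block), "+")], cls)

    # non-coding transcripts flagged coding by a supplied protein hit
    for i in range(spec.n_coding_by_hit):
        block = _noncoding_dna(rng, 400)
        s = emit(block)
        tid = f"PHIT{i+1}"
        add_tx(tid, [GenomicInterval(chrom, s, s + 400, "+")], "rejected_coding")
        protein_hits[tid] = [float(10.0 ** -rng.integers(6, 30))]

    # short transcripts
    for i in range(spec.n_short):
        n = int(rng.integers(60, 200))  # spliced length <= 200 after planting
        block = _noncoding_dna(rng, n)
        s = emit(block)
        add_tx(f"SHORT{i+1}", [GenomicInterval(chrom, s, s + n, "+")], "rejected_short")

    # TE-derived transcripts (mutated copies of database families)
    for i in range(spec.n_te):
        fam = te_families[i % len(te_families)]
        while True:
            block = _mutate_subs(rng, fam.seq, spec.te_mutation_rate)
            if find_longest_orf(block) <= 100:
                break
        s = emit(block)
        add_tx(f"TE{i+1}", [GenomicInterval(chrom, s, s + len(block), "+")], "TE_derived")

    # gene-overlapping transcripts: a gene block hosts the gene plus one transcript
    def plant_overlap(i: int, kind: str) -> None:
        gene_strand = "+" if rng.random() < 0.5 else "-"
        if kind == "SOT":
            tx_strand = gene_strand
        elif kind == "AOT":
            tx_strand = "+" if gene_strand == "-" else "-"
        else:
            tx_strand = "."
        while True:
            block = _noncoding_dna(rng, 900)
            s_try = offset
            e1 = GenomicInterval(chrom, s_try + 100, s_try + 320, tx_strand)
            e2 = GenomicInterval(chrom, s_try + 420, s_try + 700, tx_strand)
            exons = [e1] if kind == "AMB" else [e1, e2]
            spliced = "".join(block[e.start - s_try : e.end - s_try] for e in exons)
            if tx_strand == "-":
                spliced = revcomp(spliced)
            if find_longest_orf(spliced) <= 100:
                break
        s = emit(block)
        genes.append(
            TranscriptModel(
                f"GENE.{kind}{i+1}", f"GENE.{kind}{i+1}",
                [GenomicInterval(chrom, s + 50, s + 850, gene_strand)],
            )
        )
        cls = {"SOT": "SOT", "AOT": "AOT", "AMB": "ambiguous_overlap"}[kind]
        add_tx(f"{kind}{i+1}", exons, cls)

    for i in range(spec.n_sot):
        plant_overlap(i, "SOT")
    for i in range(spec.n_aot):
        plant_overlap(i, "AOT")
    for i in range(spec.n_ambiguous):
        plant_overlap(i, "AMB")

    # intergenic lincRNAs
    for i in range(spec.n_lincrna):
        strand = "+" if rng.random() < 0.5 else "-"
        n = int(rng.integers(300, 600))
        while True:
            block = _noncoding_dna(rng, n)
            if strand == "+" or find_longest_orf(revcomp(block)) <= 100:
                break
        s = emit(block)
        tid = f"LINC{i+1}"
        iv = GenomicInterval(chrom, s, s + n, strand)
        cage = i < spec.n_cage
        known_ov = i < spec.n_known_overlap
        add_tx(tid, [iv], "lincRNA", cage_plus=cage, known_overlap=known_ov)
        if cage:
            five = iv.start if strand == "+" else iv.end - 1
            tss.append((GenomicInterval(chrom, five, five + 1, strand), f"TSS.{tid}"))
        if known_ov:
            known.append(
                TranscriptModel(
                    f"KNOWN{i+1}", f"KNOWN{i+1}",
                    [GenomicInterval(chrom, max(0, s - 20), s + n + 20, strand)],
                )
            )

    pieces.append(_rand_dna(rng, 500))
    genome_seq = "".join(pieces)

    genome_path = out_dir / "genome.fasta"
    write_fasta([SequenceRecord(chrom, genome_seq)], genome_path)
    gtf_path = out_dir / "transcripts.gtf"
    write_transcript_gtf(transcripts, gtf_path)
    annot_path = out_dir / "annotation.gff"
    write_gff(genes, annot_path)
    tss_path = out_dir / "tss.bed"
    write_bed(tss, tss_path)
    te_path = None
    if te_families:
        te_path = out_dir / "te_db.fasta"
        write_fasta(te_families, te_path)
    known_path = None
    if known:
        known_path = out_dir / "known_lincrnas.gff"
        write_gff(known, known_path)

    truth = pd.DataFrame(truth_rows)
    for col, default in (("cage_plus", False), ("known_overlap", False)):
        if col not in truth.columns:
            truth[col] = default
        truth[col] = truth[col].map(lambda v: bool(v) if pd.notna(v) else False)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    hits_path = None
    if protein_hits:
        hits_path = out_dir / "protein_hits.tsv"
        with open(hits_path, "w") as fh:
            fh.write("transcript_id\tevalue\n")
            for tid, evs in protein_hits.items():
                for e in evs:
                    fh.write(f"{tid}\t{e:g}\n")
    return IdentifyFixture(
        out_dir, genome_path, gtf_path, annot_path, te_path, tss_path,
        known_path, truth, protein_hits, hits_path,
    )


# ---------------------------------------------------------------------------
# panel fixture

@dataclass
class PanelFixture:
    out_dir: Path
    seed: int
    species: list[str]
    genome_paths: dict[str, Path]
    species_list: Path
    species_tree: Path
    queries: Path
    query_loci: dict[str, GenomicInterval]
    truth: pd.DataFrame

    def decoy_queries(self, n: int, length: int = 400) -> list[SequenceRecord]:
        """Random sequences absent from every genome (separate seed stream)."""
        rng = np.random.default_rng((self.seed * 7919 + 104729) % 2**31)
        return [SequenceRecord(f"DECOY{i+1}", _rand_dna(rng, length)) for i in range(n)]


def _species_names(n: int) -> list[str]:
    return [f"Sp{chr(ord('A') + i)}" for i in range(n)]


def _ladder_newick(names: list[str], bl: float) -> str:
    t = f"{names[0]}:{bl}"
    t = f"({t},{names[1]}:{bl}):{bl}"
    for nm in names[2:]:
        t = f"({t},{nm}:{bl}):{bl}"
    return t.rsplit(":", 1)[0] + ";"


def _evolve_branch(
    rng: np.random.Generator,
    genome: str,
    tracked: list[int],
    sub_rate: float,
    indel_rate: float,
) -> tuple[str, list[int]]:
    """One branch of evolution: substitutions then single-event indels with
    geometric(0.5) lengths; tracked positions are lifted through the indels."""
    seq = _mutate_subs(rng, genome, sub_rate)
    if indel_rate <= 0:
        return seq, list(tracked)
    n_events = rng.poisson(indel_rate * len(seq))
    if n_events == 0:
        return seq, list(tracked)
    positions = np.sort(rng.integers(0, len(seq), n_events))
    events = []  # (pos, delta, length) delta>0 insertion, delta<0 deletion
    for p in positions:
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5:
            events.append((int(p), length, _rand_dna(rng, length)))
        else:
            events.append((int(p), -length, None))
    out = []
    new_tracked = {}
    cursor = 0
    shift = 0
    ti = 0
    tracked_sorted = sorted(range(len(tracked)), key=lambda i: tracked[i])

    def lift_until(limit: int) -> None:
        nonlocal ti
        while ti < len(tracked_sorted) and tracked[tracked_sorted[ti]] <= limit:
            idx = tracked_sorted[ti]
            new_tracked[idx] = tracked[idx] + shift
            ti += 1

    for pos, delta, ins in events:
        if pos < cursor:
            continue  # events inside a prior deletion are dropped
        lift_until(pos)
        out.append(seq[cursor:pos])
        if delta > 0:
            out.append(ins)
            shift += delta
            cursor = pos
        else:
            cut = min(len(seq), pos - delta)
            # tracked positions inside the deleted window clamp to its start
            while ti < len(tracked_sorted) and tracked[tracked_sorted[ti]] <= cut:
                idx = tracked_sorted[ti]
                new_tracked[idx] = pos + shift
                ti += 1
            shift -= cut - pos
            cursor = cut
    lift_until(len(seq))
    out.append(seq[cursor:])
    lifted = [new_tracked[i] for i in range(len(tracked))]
    return "".join(out), lifted


def make_panel_fixture(spec: FixtureSpec, out_dir: str | Path) -> PanelFixture:
    """Evolve an ancestral genome along a ladder tree into per-species
    genomes; write genomes, ranked species list, species tree, query FASTA
    and a truth table of planted homolog coordinates."""
    out_dir = Path(out_dir)
    (out_dir / "genomes").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    names = _species_names(spec.n_species)

    # ancestral genome with planted loci
    pieces: list[str] = []
    offset = 0
    bounds: list[int] = []  # 2 tracked positions per locus
    qids = [f"LINC{i+1:03d}" for i in range(spec.n_panel_queries)]
    pieces.append(_rand_dna(rng, spec.panel_spacer))
    offset += spec.panel_spacer
    for _q in qids:
        locus = _noncoding_dna(rng, spec.locus_length)
        bounds.extend([offset, offset + len(locus)])
        pieces.append(locus)
        offset += len(locus)
        pieces.append(_rand_dna(rng, spec.panel_spacer))
        offset += spec.panel_spacer
    ancestor = "".join(pieces)

    # deep-loss plan: shallow queries are absent beyond shallow_depth
    loss_plan = {q: set(v) for q, v in spec.loss_species.items()}
    n_shallow = int(round(spec.fraction_shallow * len(qids)))
    for q in qids[-n_shallow:] if n_shallow else []:
        loss_plan.setdefault(q, set()).update(names[spec.shallow_depth :])
    dup_plan = {q: set(v) for q, v in spec.duplication_species.items()}

    # evolve along the ladder: each internal branch mutates the running
    # ancestor; each leaf branch mutates once more
    leaves: dict[str, tuple[str, list[int]]] = {}
    lineage, tracked = ancestor, bounds
    for depth in range(spec.n_species - 1, 0, -1):
        leaf = names[depth]
        g, t = _evolve_branch(rng, lineage, tracked, spec.substitution_rate, spec.indel_rate)
        leaves[leaf] = (g, t)
        if depth > 1:
            lineage, tracked = _evolve_branch(
                rng, lineage, tracked, spec.substitution_rate, spec.indel_rate
            )
    leaves[names[0]] = _evolve_branch(
        rng, lineage, tracked, spec.substitution_rate, spec.indel_rate
    )

    truth_rows: list[dict] = []
    genome_paths: dict[str, Path] = {}
    query_records: list[SequenceRecord] = []
    query_loci: dict[str, GenomicInterval] = {}
    for rank, name in enumerate(names, 1):
        g, t = leaves[name]
        loci = {
            q: (t[2 * i], t[2 * i + 1]) for i, q in enumerate(qids)
        }
        # planted losses: delete the locus, right-to-left to keep coordinates valid
        lost = [q for q in qids if name in loss_plan.get(q, ())]
        for q in sorted(lost, key=lambda q: -loci[q][0]):
            s, e = loci.pop(q)
            g = g[:s] + g[e:]
            loci = {
                k: (a - (e - s) if a >= e else a, b - (e - s) if b >= e else b)
                for k, (a, b) in loci.items()
            }
        # planted duplications: insert a lightly mutated copy far from the original
        copies = {q: [se] for q, se in loci.items()}
        for q in qids:
            if name not in dup_plan.get(q, ()) or q not in loci:
                continue
            s, e = loci[q]
            copy = _mutate_subs(rng, g[s:e], 0.01)
            ins = len(g) - 300 if s < len(g) // 2 else 300
            g = g[:ins] + copy + g[ins:]
            shift = len(copy)
            copies = {
                k: [
                    (a + shift if a >= ins else a, b + shift if b >= ins else b)
                    for (a, b) in v
                ]
                for k, v in copies.items()
            }
            loci = {k: v[0] for k, v in copies.items()}
            copies[q] = sorted(copies[q] + [(ins, ins + shift)])
        for q in qids:
            present = q in copies and name not in loss_plan.get(q, ())
            spans = copies.get(q, []) if present else []
            truth_rows.append(
                dict(
                    query_id=q, species=name, rank=rank, present=present,
                    copy_number=len(spans),
                    coords=";".join(f"{a}-{b}" for a, b in spans),
                )
            )
        path = out_dir / "genomes" / f"{name}.fasta"
        write_fasta([SequenceRecord(f"{name}chr1", g)], path)
        genome_paths[name] = path
        if rank == 1:
            for i, q in enumerate(qids):
                s, e = loci[q]
                query_records.append(SequenceRecord(q, g[s:e]))
                query_loci[q] = GenomicInterval(f"{name}chr1", s, e, "+")

    species_list = out_dir / "species.txt"
    with open(species_list, "w") as fh:
        fh.write("\n".join(names) + "\n")
    tree_path = out_dir / "species_tree.newick"
    with open(tree_path, "w") as fh:
        fh.write(_ladder_newick(names, spec.substitution_rate) + "\n")
    queries_path = out_dir / "queries.fasta"
    write_fasta(query_records, queries_path)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth_panel.tsv", sep="\t", index=False)
    return PanelFixture(
        out_dir, spec.seed, names, genome_paths, species_list, tree_path,
        queries_path, query_loci, truth,
    )
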