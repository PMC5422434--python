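"""Homolog families across a ranked genome panel.

For every query lincRNA and every target species: search, merge hits into
loci, pick the top-hit locus (TBH), fall back to 200-nt segmented searches
when nothing passes, and keep the locus only if it survives the reciprocity
test (its sequence, searched back against the query genome, must return a top
hit overlapping the original query locus).  Reciprocal TBHs are assembled
into per-query families, labelled against optional per-species annotations,
summarised by conservation depth, and projected back onto query coordinates
for genome-browser display.
"""

from __future__ import annotations

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
    project_to_genome,
    read_annotation_gff,
    read_fasta,
    write_bed,
)
from .search import (
    MergedLocus,
    extract_locus_sequence,
    map_segment_hits,
    merge_hits,
    reciprocity_test,
    segment_query,
    select_tbh,
)

log = logging.getLogger(__name__)

HOMOLOG = "Homolog"
KNOWN_GENE = "Known_gene"
KNOWN_LINCRNA = "Known_lincRNA"


@dataclass
class SpeciesEntry:
    name: str
    genome_path: Path
    annotation_path: Path | None = None
    known_lincrna_path: Path | None = None


@dataclass
class SpeciesPanel:
    """Ordered species entries, first = query species, order = increasing
    phylogenetic distance from it."""

    entries: list[SpeciesEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("species panel is empty")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("species panel names must be unique")

    @property
    def query_species(self) -> SpeciesEntry:
        return self.entries[0]

    @property
    def targets(self) -> list[SpeciesEntry]:
        return self.entries[1:]

    def rank(self, species: str) -> int:
        for i, e in enumerate(self.entries, 1):
            if e.name == species:
                return i
        raise KeyError(species)

    @classmethod
    def from_file(
        cls, path: str | Path, genome_dir: str | Path | None = None
    ) -> "SpeciesPanel":
        """Read the ranked single-column species list.

        Plain lines name species whose genomes live at
        ``<genome_dir>/<name>.fasta``; tab-separated lines may instead give
        ``name<TAB>genome[<TAB>annotation[<TAB>known_lincRNAs]]`` explicitly.
        """
        path = Path(path)
        base = Path(genome_dir) if genome_dir else path.parent / "genomes"
        entries: list[SpeciesEntry] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                name = parts[0]
                genome = Path(parts[1]) if len(parts) > 1 and parts[1] else base / f"{name}.fasta"
                annot = Path(parts[2]) if len(parts) > 2 and parts[2] else None
                known = Path(parts[3]) if len(parts) > 3 and parts[3] else None
                entries.append(SpeciesEntry(name, genome, annot, known))
        if not entries:
            raise ValueError(f"species list {path} contains no species")
        return cls(entries)


@dataclass
class HomologCall:
    """One species' reciprocal top-hit locus for one query lincRNA."""

    species: str
    locus: GenomicInterval
    sequence: str
    reciprocal: bool
    labels: set[str] = field(default_factory=set)
    feature_ids: list[str] = field(default_factory=list)
    query_intervals: list[tuple[int, int]] = field(default_factory=list)
    copy_index: int = 1  # >1 for additional reciprocal loci (paralog copies)

    def __post_init__(self) -> None:
        if self.reciprocal:
            self.labels.add(HOMOLOG)
        elif HOMOLOG in self.labels:
            raise ValueError("Homolog label requires a reciprocal call")

    @property
    def leaf_label(self) -> str:
        return self.species if self.copy_index == 1 else f"{self.species}#{self.copy_index}"


@dataclass
class LincRNAFamily:
    query_id: str
    query_seq: str
    calls: list[HomologCall] = field(default_factory=list)  # panel order
    extra_copies: list[HomologCall] = field(default_factory=list)
    alignment: list[tuple[str, str]] | None = None
    gene_tree: object | None = None

    def call_for(self, species: str) -> HomologCall | None:
        for c in self.calls:
            if c.species == species:
                return c
        return None

    @property
    def species_with_homolog(self) -> list[str]:
        return [c.species for c in self.calls]


@dataclass
class FamilyBuildResult:
    families: dict[str, LincRNAFamily]
    raw_loci: dict[str, list[MergedLocus]]  # species -> all merged loci passing cutoff
    warnings: list[str]


def _load_genome(entry: SpeciesEntry) -> list[SequenceRecord] | None:
    try:
        return read_fasta(entry.genome_path)
    except (OSError, ValueError) as exc:
        log.warning("skipping species %s: %s", entry.name, exc)
        return None


def locate_queries(
    queries: list[SequenceRecord],
    query_genome: list[SequenceRecord],
    engine,
    cfg: Config,
) -> dict[str, GenomicInterval]:
    """Find each query's own genomic locus (TBH against the query genome);
    used for the reciprocity test when coordinates were not supplied."""
    loci: dict[str, GenomicInterval] = {}
    for q in queries:
        hits = engine.search([q], query_genome, cfg)
        tbh = select_tbh(merge_hits(hits, cfg))
        if tbh is not None:
            loci[q.id] = tbh.span
    return loci


def build_families(
    queries: list[SequenceRecord],
    panel: SpeciesPanel,
    engine,
    cfg: Config,
    evalue_cutoff: float | None = None,
    query_loci: dict[str, GenomicInterval] | None = None,
    include_paralogs: bool = False,
    max_copies_per_species: int = 3,
) -> FamilyBuildResult:
    """Build one family per query across the panel.

    Species without a passing reciprocal TBH are simply absent from the
    family.  With ``include_paralogs``, additional non-overlapping reciprocal
    loci in a species become extra gene copies (for duplication analysis).
    Each query is processed independently, so partitioning the query set and
    concatenating results reproduces a single run exactly.
    """
    cutoff = cfg.search_evalue if evalue_cutoff is None else evalue_cutoff
    warnings: list[str] = []
    query_genome = _load_genome(panel.query_species)
    if query_genome is None:
        raise ValueError(
            f"query-species genome unreadable: {panel.query_species.genome_path}"
        )
    if query_loci is None:
        query_loci = locate_queries(queries, query_genome, engine, cfg)

    families = {q.id: LincRNAFamily(q.id, q.seq) for q in queries}
    raw_loci: dict[str, list[MergedLocus]] = {}

    for entry in panel.targets:
        genome = _load_genome(entry)
        if genome is None:
            warnings.append(f"species {entry.name} skipped: unreadable genome")
            continue
        genome_dict = {r.id: r.seq for r in genome}
        annot = (
            read_annotation_gff(entry.annotation_path)
            if entry.annotation_path
            else None
        )
        known = _known_lincrna_annotation(entry, genome, engine, cfg)
        species_loci: list[MergedLocus] = []
        for q in queries:
            hits = engine.search([q], genome, cfg, cutoff)
            loci = merge_hits(hits, cfg)
            if not loci:
                segments = segment_query(q, cfg)
                seg_hits = map_segment_hits(engine.search(segments, genome, cfg, cutoff))
                loci = merge_hits(seg_hits, cfg)
            species_loci.extend(loci)
            tbh = select_tbh(loci)
            if tbh is None:
                continue
            qlocus = query_loci.get(q.id)
            if qlocus is None:
                warnings.append(
                    f"query {q.id}: no genomic locus in query genome; "
                    f"reciprocity skipped for {entry.name}"
                )
                continue
            candidates = [tbh]
            if include_paralogs:
                for loc in loci[1:]:
                    if len(candidates) >= max_copies_per_species:
                        break
                    if all(
                        not loc.span.overlaps(c.span)
                        and _gap(loc, c) > 0
                        for c in candidates
                    ):
                        candidates.append(loc)
            copy_index = 0
            for locus in candidates:
                if not reciprocity_test(
                    locus, genome_dict, query_genome, qlocus, engine, cfg, cutoff
                ):
                    continue
                copy_index += 1
                call = HomologCall(
                    species=entry.name,
                    locus=locus.span,
                    sequence=extract_locus_sequence(genome_dict, locus.span),
                    reciprocal=True,
                    query_intervals=sorted(
                        (h.query_start, h.query_end) for h in locus.hits
                    ),
                    copy_index=copy_index,
                )
                label_homolog(call, annot, known)
                if copy_index == 1:
                    families[q.id].calls.append(call)
                else:
                    families[q.id].extra_copies.append(call)
        raw_loci[entry.name] = species_loci
    return FamilyBuildResult(families, raw_loci, warnings)


def _gap(a: MergedLocus, b: MergedLocus) -> int:
    if a.subject_seq_id != b.subject_seq_id:
        return 1 << 30
    return max(a.start, b.start) - min(a.end, b.end)


def _known_lincrna_annotation(
    entry: SpeciesEntry, genome: list[SequenceRecord], engine, cfg: Config
) -> AnnotationSet | None:
    """Known-lincRNA loci for a species: GFF used directly, FASTA located on
    the genome via the search engine (TBH span per record)."""
    path = entry.known_lincrna_path
    if path is None:
        return None
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3", ".gtf"):
        return read_annotation_gff(path)
    records = read_fasta(path)
    annot = AnnotationSet()
    for rec in records:
        hits = engine.search([rec], genome, cfg)
        tbh = select_tbh(merge_hits(hits, cfg))
        if tbh is not None:
            annot.add(TranscriptModel(rec.id, rec.id, [tbh.span]))
    return annot


def label_homolog(
    call: HomologCall,
    annotation: AnnotationSet | None,
    known_lincrnas: AnnotationSet | None,
) -> HomologCall:
    """Add Known_gene / Known_lincRNA labels for overlaps with the species'
    annotation; all overlapping feature identities are retained (coordinate
    order), the first one leads in FASTA ids."""
    for annot, label in ((annotation, KNOWN_GENE), (known_lincrnas, KNOWN_LINCRNA)):
        if annot is None:
            continue
        overlapping = annot.overlapping(call.locus)
        if overlapping:
            call.labels.add(label)
            call.feature_ids.extend(
                t.transcript_id
                for t in sorted(overlapping, key=lambda t: (t.span.start, t.transcript_id))
            )
    return call


# ---------------------------------------------------------------------------
# summaries and projections

def conservation_summary(
    families: dict[str, LincRNAFamily], panel: SpeciesPanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species homolog counts/percentages (bar-chart table) and per-query
    conservation depth (the farthest panel rank with a reciprocal homolog)."""
    n_queries = len(families)
    species_rows = []
    for entry in panel.targets:
        n = sum(1 for f in families.values() if f.call_for(entry.name) is not None)
        species_rows.append(
            dict(
                species=entry.name,
                rank=panel.rank(entry.name),
                homologs=n,
                percent=round(100.0 * n / n_queries, 2) if n_queries else 0.0,
            )
        )
    query_rows = []
    for qid in sorted(families):
        f = families[qid]
        ranks = [panel.rank(c.species) for c in f.calls]
        deepest = max(ranks) if ranks else 1
        deepest_sp = (
            panel.entries[deepest - 1].name if ranks else panel.query_species.name
        )
        features = sorted(
            {fid for c in f.calls for fid in c.feature_ids}
        )
        query_rows.append(
            dict(
                query_id=qid,
                n_homologs=len(f.calls),
                deepest_species=deepest_sp,
                deepest_rank=deepest,
                overlapping_features=";".join(features),
            )
        )
    return pd.DataFrame(species_rows), pd.DataFrame(query_rows)


def query_centric_bed(
    family: LincRNAFamily,
    query_model: TranscriptModel | None,
) -> list[tuple[GenomicInterval, str]]:
    """Conserved-region BED on the query genome: each species' hit intervals
    on the query transcript, projected through the exon map (one line per
    species x contiguous block).  Without an exon map the records stay in
    transcript coordinates with a warning."""
    out: list[tuple[GenomicInterval, str]] = []
    for call in family.calls:
        blocks = _merge_intervals(call.query_intervals)
        for t0, t1 in blocks:
            if query_model is None:
                out.append(
                    (GenomicInterval(family.query_id, t0, t1, "."), call.species)
                )
                continue
            for iv in project_to_genome(
                query_model.exons, query_model.strand, t0, t1
            ):
                out.append((iv, call.species))
    if family.calls and query_model is None:
        log.warning(
            "query %s has no genomic exon map; BED is in transcript coordinates",
            family.query_id,
        )
    return out


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# output bundle

def write_family_outputs(
    result: FamilyBuildResult,
    panel: SpeciesPanel,
    out_dir: str | Path,
    query_models: dict[str, TranscriptModel] | None = None,
) -> None:
    """Write per-family FASTA, summary tables, bar-chart TSV, query-centric
    BED and per-species merged-hit GFFs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fam_dir = out_dir / "families"
    fam_dir.mkdir(exist_ok=True)
    from .core_io import write_fasta as _wf

    for qid in sorted(result.families):
        fam = result.families[qid]
        records = [SequenceRecord(qid, fam.query_seq)]
        for call in fam.calls + fam.extra_copies:
            rid = call.leaf_label + "".join(
                f"-{l}" for l in sorted(call.labels)
            )
            if call.feature_ids:
                rid += "-" + call.feature_ids[0]
            records.append(SequenceRecord(rid, call.sequence))
        _wf(records, fam_dir / f"{qid}_alignment.FASTA")

    per_species, per_query = conservation_summary(result.families, panel)
    per_query.to_csv(out_dir / "final_summary_table.tsv", sep="\t", index=False)
    per_species.to_csv(out_dir / "homolog_counts_barchart.tsv", sep="\t", index=False)

    bed_rows: list[tuple[GenomicInterval, str]] = []
    for qid in sorted(result.families):
        model = (query_models or {}).get(qid)
        bed_rows.extend(query_centric_bed(result.families[qid], model))
    write_bed(bed_rows, out_dir / "query_centric_conservation.bed")

    hs_dir = out_dir / "Homology_search"
    hs_dir.mkdir(exist_ok=True)
    for species, loci in result.raw_loci.items():
        with open(hs_dir / f"{species}.out.merged.gff", "w") as fh:
            fh.write("##gff-version 3\n")
            for loc in sorted(loci, key=lambda l: (l.subject_seq_id, l.start, l.query_id)):
                fh.write(
                    f"{loc.subject_seq_id}\tlinckit\tmatch\t{loc.start + 1}\t{loc.end}\t"
                    f"{loc.total_bitscore:.1f}\t{loc.strand}\t.\t"
                    f"ID={loc.query_id};evalue={loc.min_evalue:.3g}\n"
                )
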