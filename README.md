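# linckit

Identification of long intergenic non-coding RNAs (lincRNAs) from assembled
transcriptomes, and tracing of their conservation across a ranked panel of
genomes.

## Who this is for

LincRNAs are transcripts longer than 200 nt with low protein-coding potential
that do not overlap annotated genes. They are abundant, poorly conserved in
sequence, and mostly unannotated outside a handful of model species, which
makes both their discovery and their comparative analysis awkward to do by
hand. `linckit` packages the two halves of that workflow:

1. **Identification** (`linckit identify`): partition a transcript assembly
   (GTF) into lincRNAs, sense/antisense gene-overlapping transcripts
   (SOT/AOT), transposable-element-derived lncRNAs, and rejected
   (short/coding) transcripts, with TSS support flags and reconciliation
   against previously curated lincRNA sets.
2. **Conservation** (`linckit homology`): for each query lincRNA, find the
   top-hit locus (TBH) in each genome of a species panel ordered by
   phylogenetic distance, demand reciprocity (the TBH searched back against
   the query genome must return the query locus), group survivors into
   per-query families, summarise conservation depth, and reconcile family
   gene trees with the species tree to call duplications and losses.

## The statistics at the core

Transcripts are called coding when their longest complete ORF exceeds 100
amino acids or a protein-database hit reaches E ≤ 1e-5; TE-derived when
similarity to a user TE database reaches bit score ≥ 200 **and** E ≤ 1e-20.

Homology search uses a k-mer seeded local aligner (word size 11, match +2,
mismatch −3, gap open 5, gap extend 2) whose significance follows ungapped
Karlin–Altschul statistics: for a local alignment of raw score *S* against a
search space of *m*·*n* residue pairs,

    S' = (λS − ln K) / ln 2          E = K·m·n·e^(−λS)

with λ the positive solution of Σᵢ pᵢ e^(λsᵢ) = 1 and K from the standard
ungapped approximation. Hits within 10 kb on the same strand are merged into
a single locus scored by the summed bit scores (the multi-exon case), and
queries with no passing locus are re-searched as non-overlapping 200-nt
segments. Duplication/loss reconciliation maps each gene-tree node to the
LCA of its leaf species in the species tree; a node is a duplication when it
maps to the same species-tree node as one of its children, and gene-tree
edges under 70% bootstrap support are collapsed and re-resolved toward
minimum duplications + losses before mapping.

## Worked example

Generate a small synthetic assembly with planted classes and run the
identification pipeline:

```
linckit fixtures identify --seed 7 -o demo/fx
linckit identify \
    --gtf demo/fx/transcripts.gtf --genome demo/fx/genome.fasta \
    --annotation demo/fx/annotation.gff --te-db demo/fx/te_db.fasta \
    --tss demo/fx/tss.bed --known-lincrna demo/fx/known_lincrnas.gff \
    -o demo/out
```

The log reports the per-class partition of the 50 input transcripts:

```
INFO linckit: AOT: 5 transcripts
INFO linckit: SOT: 5 transcripts
INFO linckit: TE_derived: 5 transcripts
INFO linckit: lincRNA: 10 transcripts
INFO linckit: rejected_coding: 20 transcripts
INFO linckit: rejected_short: 5 transcripts
INFO linckit: total: 50 transcripts
```

`demo/out/demographics.tsv` summarises each emitted class (isoforms, unique
loci, GC, length range):

```
lnc_class   transcripts  loci  gc_percent  min_length  max_length  mean_length
lincRNA     10           10    50.0        334         585         437.4
SOT         5            5     49.48       500         500         500.0
AOT         5            5     50.04       500         500         500.0
TE_derived  5            5     48.16       500         500         500.0
```

and `demo/out/Final_summary_table.tsv` lists every lincRNA with its length,
exon count, TSS support and any curated lincRNA it overlaps:

```
lincRNA_id                      length  exon_count  tss_support  overlapping_known_lincRNA
LINC1_overlapping_known_lncRNA  510     1           CAGE_PLUS    KNOWN1
LINC4                           449     1           CAGE_PLUS
```

Here all ten planted lincRNAs were recovered; the five whose 5′ ends sit on a
planted transcription start site carry `CAGE_PLUS`, and the three that
overlap a curated locus carry the `_overlapping_known_lncRNA` suffix with the
curated identifier recorded.

For the conservation side, `linckit fixtures panel --seed 3 -o demo/panel`
evolves a five-species genome panel with planted homologs, and

```
linckit homology --queries demo/panel/queries.fasta \
    --panel demo/panel/species.txt --species-tree demo/panel/species_tree.newick \
    -o demo/homology
```

writes per-family FASTA files, `final_summary_table.tsv` (per-query
conservation depth), a per-species homolog bar-chart table, a query-centric
conservation BED for genome browsers, per-species merged-hit GFFs under
`Homology_search/`, and reconciled gene trees annotated with `D` marks.

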