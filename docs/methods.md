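# Methods

This note documents the models, defaults and numerical choices behind
`linckit`, and what the synthetic-data generators do and do not emulate.

## Transcript classification

Every input transcript receives exactly one class, assigned by a fixed
filter order: length → coding potential → TE similarity → gene overlap →
TSS annotation → known-lincRNA reconciliation. The order matters only for
reporting (a short coding transcript is reported as short); the lincRNA set
is the intersection of all filters either way.

* **Length.** Spliced length must *exceed* 200 nt: a 200-nt transcript is
  rejected, a 201-nt transcript kept. The boundary is strict because the
  class definition is "longer than 200 nt".
* **Coding potential.** Two independent signals: the longest complete
  (ATG-initiated, stop-terminated) ORF over all six frames, strict at
  100 aa (100 aa is non-coding, 101 aa is coding; the stop codon is not
  counted); and a protein-similarity hit at E ≤ 1e-5. Protein evidence
  arrives through a pluggable contract — a hit table keyed by transcript id
  (`--protein-hits`) or any external protein search the user runs — because
  shipping a protein database is out of scope. The ORF finder only counts
  complete ORFs: a reading frame that runs off the transcript end scores
  zero, which is exactly why truncated assemblies of real coding genes can
  leak through this filter (the generator can reproduce that failure mode,
  see below).
* **TE similarity.** A transcript is TE-derived only when its best hit
  against the user TE database satisfies bit ≥ 200 **and** E ≤ 1e-20, a
  conjunction: both are presented as thresholds to exceed, and the
  conjunction retains weakly TE-similar transcripts (old integrations,
  exaptations) in the lincRNA set, which is the stated intent of the
  stringent cutoffs. Simple tandem di-/tri-nucleotide repeats are *not*
  filtered. With no TE database the step is skipped.
* **Gene overlap.** Genomic-span overlap against the reference annotation
  (optionally widened by a 500-nt flank to stand in for missing UTRs;
  `extend_gene_coordinates` clamps at chromosome bounds). Overlapping
  transcripts are SOT (same strand) or AOT (opposite strand). Strand must
  be known: assemblies from stranded protocols carry it; unstranded
  multi-exon transcripts get it inferred from splice-site orientation
  (GT..AG forward, CT..AC reverse; conflicting introns leave it unknown).
  Unstranded single-exon transcripts overlapping a gene are
  `AMBIGUOUS_OVERLAP` and excluded from the lincRNA output — a conservative
  reading of the strandedness requirement. Span overlap (not exonic
  overlap) is used, matching the intergenic-space framing; this is a
  configurable interpretation point.
* **TSS support.** A lincRNA is `CAGE_PLUS` when its 5′ end (span start on
  `+`, span end−1 on `-`) lies within 100 bp *inclusive* of any supplied
  TSS. Unknown-strand records fall back to the span start with a warning.
* **Known lincRNAs.** Span overlap with a curated lincRNA GFF appends
  `_overlapping_known_lncRNA` to the record id; when several curated loci
  overlap, the nearest-by-midpoint identity leads and all are listed in the
  summary table.

Unique loci are computed as the transitive closure of same-sequence,
strand-compatible (equal or unknown), exon-overlapping transcripts;
transcripts on opposite strands never share a locus even when they overlap.

## Homology search and statistics

The built-in engine finds exact k-mer seeds (word size 11) on both strands,
clusters them single-linkage on (diagonal band 64, subject gap 400), and
scores each candidate window with a local Smith–Waterman alignment under
match +2, mismatch −3, gap open 5, gap extend 2 — classic nucleotide-search
defaults, all configurable. Alignment significance uses ungapped
Karlin–Altschul statistics with uniform base composition: λ solves
Σ pᵢe^(λsᵢ) = 1 by bisection to 1e-9 (the solver reproduces published
ungapped (λ, K) values, e.g. 1.33/0.621 for +1/−2), and K follows the
standard series approximation K = λδ·e^(−2σ)/(H(1−e^(−λδ))) with σ
accumulated over 60 terms of the score-walk distribution. Search space is
m·n with n the total subject genome length. An adapter around an external
`blastn` (or `rmblastn`, useful for TE-derived queries) satisfies the same
contract and serves as an independent cross-check in the tests; the
engines select the same top locus on planted fixtures.

Hits for one query on the same subject sequence and strand within 10 kb of
each other merge into a single locus (single-linkage chaining). The default
gap is a deliberate compromise — wide enough to bridge the introns of a
multi-exon query, narrow enough not to fuse neighbouring loci at fixture
scale — and is configurable. A merged locus scores the *sum* of member bit
scores, rewarding split multi-exon hits, which is the motivation for
merging in the first place. The top-hit locus (TBH) is the highest total
bit score, ties broken by lower minimum E-value, then leftmost coordinate,
making runs fully deterministic.

Queries with no passing locus are re-searched as non-overlapping 200-nt
segments; a trailing remainder below 100 nt is discarded (short tails give
unstable E-values at genome scale). Segment hits are lifted back to parent
coordinates before merging, so segments of one locus still merge into one
TBH.

**Reciprocity.** The TBH's merged-span sequence is searched back against
the query genome; the call survives only when the top locus of that return
search overlaps the original query locus (any overlap ≥ 1 bp by default; a
minimum-fraction knob exists). Queries lacking genomic coordinates in the
query genome are located by self-search first; if that fails the
reciprocity test is skipped with a recorded warning and no homolog is
called.

## Families, conservation depth, projection

Each query yields one family: the query plus at most one reciprocal TBH per
panel species (species without one are simply absent). With
`include_paralogs`, additional non-overlapping reciprocal loci become extra
gene copies labelled `Species#2`, `Species#3` — this is how planted
duplications reach the gene tree. Per-query processing is independent, so
partitioning the query set into bins and concatenating reproduces a single
run bytewise; the tests assert this exactly.

Conservation depth is the farthest panel rank with a reciprocal homolog,
using the user's ranked species list as the distance proxy; when a species
tree is supplied the reconciliation outputs give a tree-based view. The
summary deliberately reports the raw deepest species and leaves depth
binning (genus-wide, family-wide, …) to the user. Homolog loci are also
labelled `Known_gene` / `Known_lincRNA` by span overlap against optional
per-species annotations; known lincRNAs supplied as FASTA are first located
on that species' genome via the search engine (TBH span). Conserved regions
are projected through the query's exon map back to query-genome
coordinates for browser display (one BED line per species × contiguous
block); without an exon map the BED stays in transcript coordinates with a
warning.

## Alignment, trees, reconciliation

Families are aligned with a centre-star progressive aligner (every member
globally aligned to the longest sequence, gaps propagated; every input
residue reappears in order) — deterministic and dependency-free — or with
the external `mafft` adapter (1000 refinement iterations) when preferred.
Gene trees come from neighbour joining on p-distances (gap columns excluded
pairwise) with a nonparametric bootstrap (column resampling, default 100
replicates for desk-scale runs; supports are percentages on internal
splits), midpoint-rooted. An external RAxML-style likelihood tree can be
substituted upstream; the reconciliation consumes any rooted Newick.

Reconciliation collapses gene-tree edges below 70% support into polytomies
and re-resolves them toward minimum duplications + losses (exhaustive for
polytomies of up to six children, a deterministic sequential join beyond) —
an approximation of Notung-style rearrangement, documented as such. The
final binary tree is LCA-mapped: node u is a duplication iff it maps to the
same species node as one of its children; the edge to child v contributes
max(0, d(M(u),M(v)) − 1 + [u is duplication]) losses, with d the
species-tree depth difference. The mapping cost equals a brute-force
minimum over all valid reconciliation maps on every gene tree with up to
five leaves over a three-taxon species tree (enumerated exhaustively in the
tests). Because midpoint rooting can fabricate clades that conflict with
the species tree, `root_by_duploss` re-roots a gene tree on the edge
minimising duplications + losses before reconciliation; the pipeline uses
it ahead of `reconcile`.

## Synthetic data

`make_identify_fixture` plants, in a random genome with ≥1.5-kb spacers
(comfortably beyond the 500-nt flank): coding transcripts with single
complete ORFs of 101–400 aa; non-coding transcripts flagged by a supplied
protein hit; sub-200-nt transcripts; mutated copies (2%) of a small TE
database; two-exon transcripts overlapping planted genes in sense,
antisense, or unstranded-single-exon (ambiguous) configuration; and
intergenic lincRNAs of 300–600 nt, some with a TSS planted at the 5′ end
and some overlapping a curated-lincRNA GFF. Every planted non-coding
sequence is rejection-sampled to carry no ORF above 100 aa, including
across spliced junctions. Setting `truncate_coding_aa` (e.g. 95) plants
complete sub-100-aa ORFs instead, reproducing how incomplete assemblies of
real coding genes pass the coding filter.

`make_panel_fixture` evolves an ancestral genome with planted ~500-nt loci
along a ladder species tree (default five species, 0.03 substitutions/site
per branch — comfortably inside the detection range of the seeded aligner —
and 5e-4 indels/site as single events of geometric length, with planted
locus boundaries lifted through every indel). Chosen loci are deleted on
chosen species (planted losses; a `fraction_shallow` knob deletes a
fraction of loci everywhere beyond a given rank) or duplicated as a lightly
mutated copy inserted far from the original. Queries are the loci of the
first species; decoy queries are fresh random sequences. Truth tables
record class, flags, presence, copy number and coordinates throughout.

What the generators do *not* emulate: realistic codon usage and ORF
conservation, repeat landscapes beyond a toy TE database, transcript-level
noise (assembly fragmentation except via the truncation knob, isoform
variation), rate heterogeneity across sites and branches, and genome
rearrangement. Passing tests therefore demonstrate the correctness of the
filtering logic, the search statistics and the reconciliation machinery
under controlled conditions — not recall on real RNA-seq assemblies, where
assembly quality and annotation completeness dominate.

## Problem sizes and determinism

Test and acceptance runs use desk-scale inputs chosen as the package's
own operating points: ~200–600-transcript assemblies, 30–40-kb genomes,
panels of five species with 20 queries, 100 bootstrap replicates. All
randomness flows from explicit integer seeds (numpy `default_rng`); the
same seed reproduces every output byte for byte, and the fixture
generators, engines and writers avoid unordered iteration throughout.

## Known limitations

* The coding filter sees only complete ORFs and supplied protein hits; it
  has no Markov coding-potential model, so ORF-free coding fragments pass.
* Karlin–Altschul parameters are ungapped; gapped E-values are slightly
  conservative under heavy gapping.
* The reconciliation approximates rearrangement by collapse-and-re-resolve;
  it does not implement edge-weight-aware rearrangement, dated
  reconciliation, or transfer events.
* Orthology beyond the reciprocal top hit is out of scope; all passing hits
  are retained in the per-species GFFs for downstream analysis.
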