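"""Nucleotide similarity search and top-hit locus logic.

The built-in engine finds exact k-mer seeds on both strands, clusters them by
diagonal, and scores each candidate region with a local (Smith-Waterman)
alignment under the configured match/mismatch/affine-gap scheme.  Raw scores
are converted to bit scores and E-values with ungapped Karlin-Altschul
statistics computed once from the scoring scheme and uniform base
composition:

    bit = (lambda * S - ln K) / ln 2        E = K * m * n * exp(-lambda * S)

An adapter around an external ``blastn`` executable satisfies the same
contract and is used as an independent cross-check in the tests.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import Align

from .core_io import Config, GenomicInterval, SequenceRecord, revcomp, write_fasta

log = logging.getLogger(__name__)

SEGMENT_SEP = ";seg="   # joins a parent query id to a segment offset


@dataclass
class AlignmentHit:
    """One local alignment between a query and a subject sequence.

    ``query_start/end`` are always in forward query coordinates; ``strand``
    is the orientation of the match relative to the subject.
    """

    query_id: str
    query_start: int
    query_end: int
    subject_seq_id: str
    subject_start: int
    subject_end: int
    strand: str
    score: float
    bitscore: float
    evalue: float
    identity: float

    def __post_init__(self) -> None:
        if self.evalue < 0 or not math.isfinite(self.bitscore):
            raise ValueError("invalid hit statistics")
        if self.query_start >= self.query_end or self.subject_start >= self.subject_end:
            raise ValueError("invalid hit intervals")

    @property
    def subject_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.subject_seq_id, self.subject_start, self.subject_end, self.strand
        )


@dataclass
class MergedLocus:
    """Non-redundant hits for one query chained into a single genomic locus."""

    query_id: str
    subject_seq_id: str
    strand: str
    hits: list[AlignmentHit]
    start: int
    end: int
    total_bitscore: float
    min_evalue: float

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.subject_seq_id, self.start, self.end, self.strand)


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics

def karlin_altschul_params(
    match: float, mismatch: float, p_match: float = 0.25
) -> tuple[float, float]:
    """Ungapped Karlin-Altschul (lambda, K) for a two-valued scoring scheme.

    lambda solves p*e^(lambda*match) + (1-p)*e^(lambda*mismatch) = 1 by
    bisection to 1e-9.  K follows the standard ungapped series approximation
    K = delta*lambda*e^(-2*sigma) / (H*(1 - e^(-lambda*delta))) with sigma
    accumulated from the partial-sum distribution of the score walk.

    Raises ValueError when the expected per-pair score is non-negative (no
    positive lambda exists).
    """
    q = 1.0 - p_match
    expected = p_match * match + q * mismatch
    if expected >= 0:
        raise ValueError("expected score per aligned pair must be negative")
    if match <= 0:
        raise ValueError("match score must be positive")

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match) + q * math.exp(lam * mismatch) - 1.0

    lo, hi = 0.0, 1.0
    while f(hi) < 0:
        hi *= 2
    for _ in range(200):
        mid = (lo + hi) / 2
        if hi - lo < 1e-9:
            break
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    lam = (lo + hi) / 2

    # lattice period of the integer score walk
    mi, ma = int(round(mismatch)), int(round(match))
    delta = math.gcd(abs(mi), abs(ma))
    # relative entropy per pair (nats)
    H = lam * (p_match * match * math.exp(lam * match) + q * mismatch * math.exp(lam * mismatch))
    # sigma = sum_j (1/j) [ P(S_j >= 0) + E(e^{lambda S_j}; S_j < 0) ]
    n_terms = 60
    step = np.zeros(ma - mi + 1)
    step[0] = q          # mismatch (most negative step)
    step[-1] = p_match   # match
    dist = np.array([1.0])  # S_0 = 0; after j convolutions index i holds score mi*j + i
    sigma = 0.0
    for j in range(1, n_terms + 1):
        dist = np.convolve(dist, step)
        scores = np.arange(len(dist)) + mi * j
        nonzero = dist > 0
        s = scores[nonzero]
        p = dist[nonzero]
        neg = s < 0
        term = p[~neg].sum() + (p[neg] * np.exp(lam * s[neg])).sum()
        sigma += term / j
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    return lam, K


@lru_cache(maxsize=32)
def _ka_cached(match: int, mismatch: int) -> tuple[float, float]:
    return karlin_altschul_params(match, mismatch)


def bit_score(raw: float, lam: float, K: float) -> float:
    return (lam * raw - math.log(K)) / math.log(2.0)


def e_value(raw: float, lam: float, K: float, m: int, n: int) -> float:
    return K * m * n * math.exp(-lam * raw)


# ---------------------------------------------------------------------------
# built-in seeded aligner

def _make_aligner(cfg: Config) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = cfg.match
    a.mismatch_score = cfg.mismatch
    # affine: a gap of length g costs gap_open + g * gap_extend
    a.open_gap_score = -(cfg.gap_open + cfg.gap_extend)
    a.extend_gap_score = -cfg.gap_extend
    return a


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    return index


def _seed_clusters(
    query: str, index: dict[str, list[int]], k: int, band: int = 64, gap: int = 400
) -> list[tuple[int, int]]:
    """Cluster seed matches into candidate subject regions.

    Seeds are grouped single-linkage on (diagonal within *band*, subject
    distance within *gap*); each cluster is returned as a subject
    (min_pos, max_pos+k) window anchor.
    """
    seeds: list[tuple[int, int]] = []  # (diag, spos)
    for i in range(len(query) - k + 1):
        positions = index.get(query[i : i + k])
        if positions:
            for s in positions:
                seeds.append((s - i, s))
    if not seeds:
        return []
    seeds.sort()
    clusters: list[tuple[int, int]] = []
    cur_diag, cur_lo, cur_hi = seeds[0][0], seeds[0][1], seeds[0][1]
    for diag, s in seeds[1:]:
        if diag - cur_diag <= band and s - cur_hi <= gap:
            cur_hi = max(cur_hi, s)
            cur_diag = diag
        else:
            clusters.append((cur_lo, cur_hi + k))
            cur_diag, cur_lo, cur_hi = diag, s, s
    clusters.append((cur_lo, cur_hi + k))
    # merge overlapping windows produced by distinct diagonal runs
    clusters.sort()
    merged: list[tuple[int, int]] = []
    for lo, hi in clusters:
        if merged and lo <= merged[-1][1] + gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def seeded_local_search(
    query: SequenceRecord,
    subject: SequenceRecord,
    cfg: Config,
    evalue_cutoff: float | None = None,
    search_space_n: int | None = None,
    _index: dict[str, list[int]] | None = None,
) -> list[AlignmentHit]:
    """Search one query against one subject sequence on both strands.

    Returns hits with E <= cutoff sorted by bit score descending.  A query
    shorter than the word size yields an empty result with a warning.
    """
    cutoff = cfg.search_evalue if evalue_cutoff is None else evalue_cutoff
    k = cfg.word_size
    if len(query) < k:
        log.warning("query %s shorter than word size %d; skipped", query.id, k)
        return []
    lam, K = _ka_cached(cfg.match, cfg.mismatch)
    n = search_space_n if search_space_n is not None else len(subject)
    m = len(query)
    index = _index if _index is not None else _kmer_index(subject.seq, k)
    aligner = _make_aligner(cfg)
    hits: list[AlignmentHit] = []
    seen: set[tuple] = set()
    for strand, qseq in (("+", query.seq), ("-", revcomp(query.seq))):
        for lo, hi in _seed_clusters(qseq, index, k):
            # seeds anchor the aligned region; the pad only needs to absorb
            # unseeded overhangs, so cap it for very long queries
            pad = min(m, 1000) + 20
            w_lo = max(0, lo - pad)
            w_hi = min(len(subject.seq), hi + pad)
            window = subject.seq[w_lo:w_hi]
            alns = aligner.align(qseq, window)
            if alns.score <= 0:
                continue
            best = alns[0]
            qa, sa = best.aligned
            q0, q1 = int(qa[0][0]), int(qa[-1][1])
            s0, s1 = int(sa[0][0]) + w_lo, int(sa[-1][1]) + w_lo
            raw = float(best.score)
            E = e_value(raw, lam, K, m, n)
            if E > cutoff:
                continue
            if strand == "-":
                q0, q1 = m - q1, m - q0
            key = (strand, q0, q1, s0, s1)
            if key in seen:
                continue
            seen.add(key)
            counts = best.counts()
            aln_len = counts.identities + counts.mismatches + counts.gaps
            hits.append(
                AlignmentHit(
                    query_id=query.id,
                    query_start=q0,
                    query_end=q1,
                    subject_seq_id=subject.id,
                    subject_start=s0,
                    subject_end=s1,
                    strand=strand,
                    score=raw,
                    bitscore=bit_score(raw, lam, K),
                    evalue=E,
                    identity=100.0 * counts.identities / aln_len if aln_len else 0.0,
                )
            )
    hits.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_seq_id, h.subject_start))
    return hits


class BuiltinSearchEngine:
    """Deterministic in-process search engine with per-genome k-mer caches."""

    def __init__(self) -> None:
        self._cache: dict[tuple, dict[str, list[int]]] = {}

    def _index_for(self, rec: SequenceRecord, k: int) -> dict[str, list[int]]:
        key = (rec.id, len(rec.seq), hash(rec.seq), k)
        idx = self._cache.get(key)
        if idx is None:
            idx = _kmer_index(rec.seq, k)
            self._cache[key] = idx
        return idx

    def search(
        self,
        queries: list[SequenceRecord],
        genome: list[SequenceRecord],
        cfg: Config,
        evalue_cutoff: float | None = None,
    ) -> list[AlignmentHit]:
        n_total = sum(len(r) for r in genome)
        hits: list[AlignmentHit] = []
        for q in queries:
            for rec in genome:
                hits.extend(
                    seeded_local_search(
                        q, rec, cfg, evalue_cutoff, n_total,
                        _index=self._index_for(rec, cfg.word_size),
                    )
                )
        hits.sort(
            key=lambda h: (h.query_id, -h.bitscore, h.evalue, h.subject_seq_id, h.subject_start)
        )
        return hits


class BlastnSearchEngine:
    """Adapter around an external ``blastn`` executable (tabular output).

    Satisfies the same contract as the built-in engine; used as an
    independent oracle in tests.  RepeatMasker-aware searches can be had by
    pointing ``executable`` at ``rmblastn``.
    """

    def __init__(self, executable: str = "blastn") -> None:
        self.executable = executable
        if shutil.which(executable) is None:
            raise RuntimeError(f"{executable} not found on PATH")

    def search(
        self,
        queries: list[SequenceRecord],
        genome: list[SequenceRecord],
        cfg: Config,
        evalue_cutoff: float | None = None,
    ) -> list[AlignmentHit]:
        cutoff = cfg.search_evalue if evalue_cutoff is None else evalue_cutoff
        with tempfile.TemporaryDirectory() as tmp:
            qf = Path(tmp) / "q.fasta"
            sf = Path(tmp) / "s.fasta"
            write_fasta(queries, qf)
            write_fasta(genome, sf)
            db = Path(tmp) / "db"
            subprocess.run(
                ["makeblastdb", "-in", str(sf), "-dbtype", "nucl", "-out", str(db)],
                check=True, capture_output=True,
            )
            out = subprocess.run(
                [
                    self.executable, "-task", "blastn",
                    "-query", str(qf), "-db", str(db),
                    "-evalue", str(cutoff),
                    "-word_size", str(cfg.word_size),
                    "-reward", str(cfg.match), "-penalty", str(cfg.mismatch),
                    "-gapopen", str(cfg.gap_open), "-gapextend", str(cfg.gap_extend),
                    "-dust", "no", "-soft_masking", "false",
                    "-outfmt", "6 qseqid sseqid pident length qstart qend sstart send evalue bitscore score",
                ],
                check=True, capture_output=True, text=True,
            ).stdout
        hits: list[AlignmentHit] = []
        for line in out.splitlines():
            f = line.split("\t")
            qs, qe = int(f[4]) - 1, int(f[5])
            ss, se = int(f[6]), int(f[7])
            strand = "+" if ss <= se else "-"
            s0, s1 = (ss - 1, se) if strand == "+" else (se - 1, ss)
            hits.append(
                AlignmentHit(
                    query_id=f[0], query_start=qs, query_end=qe,
                    subject_seq_id=f[1], subject_start=s0, subject_end=s1,
                    strand=strand, score=float(f[10]), bitscore=float(f[9]),
                    evalue=float(f[8]) if float(f[8]) > 0 else 1e-300,
                    identity=float(f[2]),
                )
            )
        hits.sort(
            key=lambda h: (h.query_id, -h.bitscore, h.evalue, h.subject_seq_id, h.subject_start)
        )
        return hits


# ---------------------------------------------------------------------------
# merging, TBH, segmentation, reciprocity

def merge_hits(hits: list[AlignmentHit], cfg: Config) -> list[MergedLocus]:
    """Chain hits for one query into merged loci.

    Hits on the same subject sequence and strand whose subject intervals lie
    within ``cfg.merge_gap`` of each other are chained single-linkage (the
    typical multi-exon case); the merged locus scores the sum of member bit
    scores.  Output order is total bit score descending and is independent of
    input hit order.
    """
    if not hits:
        return []
    qids = {h.query_id for h in hits}
    if len(qids) > 1:
        raise ValueError(f"merge_hits expects hits for one query, got {sorted(qids)}")
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.subject_seq_id, h.strand), []).append(h)
    loci: list[MergedLocus] = []
    for (sid, strand), members in groups.items():
        members.sort(key=lambda h: (h.subject_start, h.subject_end))
        chain: list[AlignmentHit] = []
        chain_end = -1
        for h in members:
            if chain and h.subject_start - chain_end > cfg.merge_gap:
                loci.append(_finish_locus(chain, sid, strand))
                chain = []
            chain.append(h)
            chain_end = max(chain_end, h.subject_end)
        if chain:
            loci.append(_finish_locus(chain, sid, strand))
    loci.sort(
        key=lambda l: (-l.total_bitscore, l.min_evalue, l.subject_seq_id, l.start)
    )
    return loci


def _finish_locus(chain: list[AlignmentHit], sid: str, strand: str) -> MergedLocus:
    return MergedLocus(
        query_id=chain[0].query_id,
        subject_seq_id=sid,
        strand=strand,
        hits=list(chain),
        start=min(h.subject_start for h in chain),
        end=max(h.subject_end for h in chain),
        total_bitscore=sum(h.bitscore for h in chain),
        min_evalue=min(h.evalue for h in chain),
    )


def select_tbh(loci: list[MergedLocus]) -> MergedLocus | None:
    """The top-hit locus: highest total bit score, ties by lower minimum
    E-value, then leftmost (seq_id, start).  None on empty input."""
    if not loci:
        return None
    return min(
        loci, key=lambda l: (-l.total_bitscore, l.min_evalue, l.subject_seq_id, l.start)
    )


def segment_query(rec: SequenceRecord, cfg: Config) -> list[SequenceRecord]:
    """Cut a query into non-overlapping segments for the fallback search.

    Segments cover [0,L), [L,2L), ... with L = cfg.segment_len; a trailing
    remainder is kept as its own segment only when at least
    cfg.min_segment_len nt (shorter tails give unstable E-values at genome
    scale).  Segment ids encode the parent id and offset.
    """
    out: list[SequenceRecord] = []
    L = cfg.segment_len
    for off in range(0, len(rec.seq), L):
        piece = rec.seq[off : off + L]
        if len(piece) < L and len(piece) < cfg.min_segment_len:
            break
        out.append(SequenceRecord(f"{rec.id}{SEGMENT_SEP}{off}", piece))
    return out


def map_segment_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Lift segment hits back to parent-query coordinates (before merging)."""
    lifted: list[AlignmentHit] = []
    for h in hits:
        if SEGMENT_SEP not in h.query_id:
            lifted.append(h)
            continue
        parent, off_s = h.query_id.rsplit(SEGMENT_SEP, 1)
        off = int(off_s)
        lifted.append(
            AlignmentHit(
                query_id=parent,
                query_start=h.query_start + off,
                query_end=h.query_end + off,
                subject_seq_id=h.subject_seq_id,
                subject_start=h.subject_start,
                subject_end=h.subject_end,
                strand=h.strand,
                score=h.score,
                bitscore=h.bitscore,
                evalue=h.evalue,
                identity=h.identity,
            )
        )
    return lifted


def extract_locus_sequence(
    genome: dict[str, str], locus: GenomicInterval
) -> str:
    """Subject-genome substring of a locus, reverse-complemented for '-'."""
    chrom = genome[locus.seq_id]
    s = chrom[locus.start : locus.end]
    return revcomp(s) if locus.strand == "-" else s


def reciprocity_test(
    tbh: MergedLocus,
    subject_genome: dict[str, str],
    query_genome: list[SequenceRecord],
    query_locus: GenomicInterval | None,
    engine,
    cfg: Config,
    evalue_cutoff: float | None = None,
) -> bool:
    """Mutual top-hit test: the TBH sequence, searched back against the query
    genome, must itself return a top hit overlapping the original query locus.

    Returns False when no reciprocal hit passes the cutoff.  A query lacking
    genomic coordinates cannot be tested; the caller should skip with a
    warning in that case (query_locus None raises here).
    """
    if query_locus is None:
        raise ValueError("query locus required for reciprocity test")
    seq = extract_locus_sequence(subject_genome, tbh.span)
    probe = SequenceRecord("reciprocal-probe", seq)
    hits = engine.search([probe], query_genome, cfg, evalue_cutoff)
    back = select_tbh(merge_hits(hits, cfg))
    if back is None:
        return False
    if back.subject_seq_id != query_locus.seq_id:
        return False
    ov = min(back.end, query_locus.end) - max(back.start, query_locus.start)
    if ov <= 0:
        return False
    return ov >= cfg.reciprocal_min_fraction * query_locus.length
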