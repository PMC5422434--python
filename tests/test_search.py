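"""Seeded local search, alignment statistics, merging, TBH and reciprocity."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from linckit.core_io import Config, GenomicInterval, SequenceRecord, revcomp
from linckit.search import (
    AlignmentHit,
    BlastnSearchEngine,
    BuiltinSearchEngine,
    e_value,
    karlin_altschul_params,
    map_segment_hits,
    merge_hits,
    merge_hits as _merge,
    reciprocity_test,
    seeded_local_search,
    segment_query,
    select_tbh,
)

BASES = np.array(list("ACGT"))


def rand_dna(rng, n):
    return "".join(rng.choice(BASES, n))


def make_hit(**kw):
    defaults = dict(
        query_id="q", query_start=0, query_end=100, subject_seq_id="chr1",
        subject_start=0, subject_end=100, strand="+", score=200.0,
        bitscore=100.0, evalue=1e-30, identity=99.0,
    )
    defaults.update(kw)
    return AlignmentHit(**defaults)


class TestKarlinAltschul:
    @pytest.mark.parametrize("match,mismatch", [(1, -2), (2, -3)])
    def test_lambda_matches_independent_root_finder(self, match, mismatch):
        lam, K = karlin_altschul_params(match, mismatch)
        f = lambda x: 0.25 * math.exp(x * match) + 0.75 * math.exp(x * mismatch) - 1.0
        oracle = brentq(f, 1e-6, 10.0, xtol=1e-12)
        assert abs(lam - oracle) < 1e-6
        assert 0 < K < 1

    def test_published_ungapped_values(self):
        # NCBI ungapped (lambda, K) for reward/penalty +1/-2 are 1.33/0.621
        lam, K = karlin_altschul_params(1, -2)
        assert lam == pytest.approx(1.33, abs=0.01)
        assert K == pytest.approx(0.621, abs=0.005)

    def test_nonnegative_expected_score_is_error(self):
        with pytest.raises(ValueError):
            karlin_altschul_params(1, 1)

    def test_evalue_strictly_decreases_with_score(self):
        lam, K = karlin_altschul_params(2, -3)
        es = [e_value(s, lam, K, 500, 100_000) for s in range(50, 500, 50)]
        assert all(a > b for a, b in zip(es, es[1:]))


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(42)
    query = rand_dna(rng, 500)
    background = rand_dna(rng, 100_000)
    subject = background[:30_000] + query + background[30_000:]
    return query, subject


class TestSeededSearch:
    def test_planted_query_found_at_exact_coordinates(self, planted):
        query, subject = planted
        hits = seeded_local_search(
            SequenceRecord("q", query), SequenceRecord("s", subject), Config()
        )
        assert len(hits) == 1
        h = hits[0]
        assert (h.subject_start, h.subject_end, h.strand) == (30_000, 30_500, "+")
        assert h.identity == 100.0
        assert h.evalue < 1e-20

    def test_reverse_complement_planting_found_on_minus(self, planted):
        query, _ = planted
        rng = np.random.default_rng(43)
        background = rand_dna(rng, 60_000)
        subject = background[:20_000] + revcomp(query) + background[20_000:]
        hits = seeded_local_search(
            SequenceRecord("q", query), SequenceRecord("s", subject), Config()
        )
        assert (hits[0].subject_start, hits[0].subject_end, hits[0].strand) == (
            20_000, 20_500, "-",
        )

    def test_random_queries_yield_no_hits_at_stringent_cutoff(self, planted):
        _, subject = planted
        engine = BuiltinSearchEngine()
        rng = np.random.default_rng(7)
        queries = [SequenceRecord(f"r{i}", rand_dna(rng, 200)) for i in range(100)]
        hits = engine.search(queries, [SequenceRecord("s", subject)], Config())
        assert hits == []

    def test_query_shorter_than_word_size_is_empty(self):
        hits = seeded_local_search(
            SequenceRecord("q", "ACGT"), SequenceRecord("s", "ACGT" * 100), Config()
        )
        assert hits == []

    def test_cutoff_monotonicity(self, planted):
        query, subject = planted
        rng = np.random.default_rng(9)
        mutated = list(query)
        for i in rng.choice(500, 100, replace=False):  # 20% divergence
            mutated[i] = rng.choice([b for b in "ACGT" if b != mutated[i]])
        q = SequenceRecord("q", "".join(mutated))
        s = SequenceRecord("s", subject)
        found = []
        for cutoff in (1e-20, 1e-10, 1e-1):
            hits = seeded_local_search(q, s, Config(), evalue_cutoff=cutoff)
            found.append({(h.subject_start, h.subject_end, h.strand) for h in hits})
        assert found[0] <= found[1] <= found[2]


class TestMergeAndTbh:
    def test_nearby_hits_merge_with_summed_score(self, cfg):
        h1 = make_hit(subject_start=1000, subject_end=1200, bitscore=150.0)
        h2 = make_hit(subject_start=1500, subject_end=1700, bitscore=250.0)
        (locus,) = merge_hits([h1, h2], cfg)
        assert (locus.start, locus.end) == (1000, 1700)
        assert locus.total_bitscore == 400.0

    def test_opposite_strands_stay_separate(self, cfg):
        h1 = make_hit(strand="+")
        h2 = make_hit(strand="-")
        assert len(merge_hits([h1, h2], cfg)) == 2

    def test_distant_hits_stay_separate(self, cfg):
        h1 = make_hit(subject_start=0, subject_end=200)
        h2 = make_hit(subject_start=50_200, subject_end=50_400)
        assert len(merge_hits([h1, h2], cfg)) == 2

    def test_order_invariance(self, cfg):
        rng = np.random.default_rng(3)
        hits = [
            make_hit(subject_start=int(s), subject_end=int(s) + 100,
                     bitscore=float(rng.integers(50, 300)))
            for s in rng.integers(0, 100_000, 12)
        ]
        ref = [(l.start, l.end, l.total_bitscore) for l in merge_hits(hits, cfg)]
        for _ in range(5):
            rng.shuffle(hits)
            got = [(l.start, l.end, l.total_bitscore) for l in merge_hits(hits, cfg)]
            assert got == ref

    def test_tbh_highest_total(self, cfg):
        a = merge_hits([make_hit(bitscore=400.0)], cfg)[0]
        b = merge_hits([make_hit(bitscore=300.0, subject_start=50_000, subject_end=50_100)], cfg)[0]
        assert select_tbh([a, b]) is a

    def test_tbh_tie_breaks_leftmost(self, cfg):
        a = merge_hits([make_hit(subject_start=9000, subject_end=9100)], cfg)[0]
        b = merge_hits([make_hit(subject_start=100, subject_end=200)], cfg)[0]
        assert select_tbh([a, b]) is b

    def test_tbh_empty(self):
        assert select_tbh([]) is None


class TestSegmentation:
    def test_650_drops_short_remainder(self, cfg):
        segs = segment_query(SequenceRecord("q", "A" * 650), cfg)
        assert [len(s.seq) for s in segs] == [200, 200, 200]

    def test_400_exact(self, cfg):
        segs = segment_query(SequenceRecord("q", "A" * 400), cfg)
        assert [len(s.seq) for s in segs] == [200, 200]

    def test_remainder_at_minimum_length_kept(self, cfg):
        segs = segment_query(SequenceRecord("q", "A" * 300), cfg)
        assert [len(s.seq) for s in segs] == [200, 100]

    def test_hits_lift_back_to_parent_coordinates(self, cfg):
        segs = segment_query(SequenceRecord("q", "A" * 400), cfg)
        h = make_hit(query_id=segs[1].id, query_start=10, query_end=60)
        (lifted,) = map_segment_hits([h])
        assert lifted.query_id == "q"
        assert (lifted.query_start, lifted.query_end) == (210, 260)


class TestReciprocity:
    def test_planted_ortholog_is_reciprocal(self, cfg):
        rng = np.random.default_rng(5)
        locus = rand_dna(rng, 400)
        qg = rand_dna(rng, 10_000)
        query_genome = [SequenceRecord("qchr", qg[:4000] + locus + qg[4000:])]
        sg = rand_dna(rng, 10_000)
        subject = [SequenceRecord("schr", sg[:7000] + locus + sg[7000:])]
        engine = BuiltinSearchEngine()
        hits = engine.search([SequenceRecord("L1", locus)], subject, cfg)
        tbh = select_tbh(merge_hits(hits, cfg))
        assert reciprocity_test(
            tbh, {r.id: r.seq for r in subject}, query_genome,
            GenomicInterval("qchr", 4000, 4400, "+"), engine, cfg,
        )

    def test_paralog_nearer_other_locus_fails(self, cfg):
        rng = np.random.default_rng(6)
        locus_a = rand_dna(rng, 400)
        locus_b = rand_dna(rng, 400)
        qg = rand_dna(rng, 12_000)
        # query genome holds A and B; subject genome holds only B
        query_genome = [
            SequenceRecord("qchr", qg[:2000] + locus_a + qg[2000:8000] + locus_b + qg[8000:])
        ]
        sg = rand_dna(rng, 10_000)
        subject = [SequenceRecord("schr", sg[:5000] + locus_b + sg[5000:])]
        engine = BuiltinSearchEngine()
        hits = engine.search([SequenceRecord("A", locus_a)], subject, cfg, 1e-1)
        tbh = select_tbh(merge_hits(hits, cfg))
        if tbh is not None:  # B is no homolog of A at all: either outcome is a fail
            assert not reciprocity_test(
                tbh, {r.id: r.seq for r in subject}, query_genome,
                GenomicInterval("qchr", 2000, 2400, "+"), engine, cfg,
            )

    def test_true_paralog_rejected_by_reciprocity(self, cfg):
        # subject's best locus reciprocally maps to query locus B, not A
        rng = np.random.default_rng(8)
        shared = rand_dna(rng, 400)
        a = shared
        b_mut = list(shared)
        for i in rng.choice(400, 8, replace=False):
            b_mut[i] = rng.choice([x for x in "ACGT" if x != b_mut[i]])
        b = "".join(b_mut)
        qg = rand_dna(rng, 24_000)
        query_genome = [
            SequenceRecord("qchr", qg[:2000] + a + qg[2000:14000] + b + qg[14000:])
        ]
        sg = rand_dna(rng, 12_000)
        subject = [SequenceRecord("schr", sg[:6000] + b + sg[6000:])]
        engine = BuiltinSearchEngine()
        hits = engine.search([SequenceRecord("B", b)], subject, cfg)
        tbh = select_tbh(merge_hits(hits, cfg))
        # reciprocal search returns B's locus: overlap with A's locus fails
        assert not reciprocity_test(
            tbh, {r.id: r.seq for r in subject}, query_genome,
            GenomicInterval("qchr", 2000, 2400, "+"), engine, cfg,
        )
        assert reciprocity_test(
            tbh, {r.id: r.seq for r in subject}, query_genome,
            GenomicInterval("qchr", 14400, 14800, "+"), engine, cfg,
        )


class TestEngineEquivalence:
    def test_builtin_and_blastn_pick_same_tbh(self, cfg):
        rng = np.random.default_rng(12)
        queries = []
        parts = []
        for i in range(8):
            q = rand_dna(rng, 450)
            mutated = list(q)
            for j in rng.choice(450, 14, replace=False):
                mutated[j] = rng.choice([b for b in "ACGT" if b != mutated[j]])
            queries.append(SequenceRecord(f"q{i}", q))
            parts.append(rand_dna(rng, 2500))
            parts.append("".join(mutated))
        parts.append(rand_dna(rng, 2500))
        genome = [SequenceRecord("chr1", "".join(parts))]
        builtin = BuiltinSearchEngine()
        blast = BlastnSearchEngine()
        agree = 0
        for q in queries:
            tb = select_tbh(merge_hits(builtin.search([q], genome, cfg), cfg))
            tn = select_tbh(merge_hits(blast.search([q], genome, cfg), cfg))
            assert tb is not None and tn is not None
            ov = min(tb.end, tn.end) - max(tb.start, tn.start)
            if ov >= 0.5 * max(tb.end - tb.start, tn.end - tn.start):
                agree += 1
        assert agree >= 0.95 * len(queries)
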