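import numpy as np
import pytest

from mhcscan.alphabet import revcomp
from mhcscan.homology_search import SearchConfig, dedupe_hits, search, search_all
from mhcscan.model import AlignmentHit, ConsensusQuery, GenomeAssembly

from .conftest import random_seq
from .oracles import brute_overlap_components, sw_local_oracle


def _query(seq, qid="II_e2_q00", cls="II", exon=2):
    return ConsensusQuery(query_id=qid, level="global", mhc_class=cls,
                          exon_label=exon, sequence=seq)


def _genome(seq, contig="c1"):
    return GenomeAssembly(assembly_id="t", contigs={contig: seq})


def _plant(rng, qseq, contig_len=50000, at=None, mutate=0.0):
    contig = random_seq(rng, contig_len)
    if at is None:
        at = contig_len // 2
    planted = qseq
    if mutate > 0:
        chars = list(qseq)
        k = int(round(mutate * len(qseq)))
        for i in rng.choice(len(qseq), size=k, replace=False):
            chars[i] = [b for b in "ACGT" if b != chars[i]][rng.integers(3)]
        planted = "".join(chars)
    return contig[:at] + planted + contig[at + len(planted):], at


class TestSearch:
    def test_verbatim_planting_single_perfect_hit(self, rng):
        qseq = random_seq(rng, 270)
        contig, at = _plant(rng, qseq)
        hits = search(_query(qseq), _genome(contig))
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 1.0
        assert (h.query_start, h.query_end) == (0, 270)
        assert (h.start, h.end) == (at, at + 270)
        assert h.strand == "+"

    def test_reverse_complement_planting_minus_strand(self, rng):
        qseq = random_seq(rng, 270)
        contig, at = _plant(rng, revcomp(qseq))
        hits = search(_query(qseq), _genome(contig))
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (at, at + 270)

    def test_mutated_planting_identity_and_span(self, rng):
        """A copy planted at 10% divergence is found near 0.90 identity."""
        qseq = random_seq(rng, 300)
        contig, at = _plant(rng, qseq, mutate=0.10)
        hits = search(_query(qseq), _genome(contig))
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == pytest.approx(0.90, abs=0.03)
        assert abs(h.start - at) <= 5 and abs(h.end - (at + 300)) <= 5

    def test_random_contig_yields_no_hits(self, rng):
        qseq = random_seq(rng, 300)
        for _ in range(5):
            contig = random_seq(rng, 100000)
            assert search(_query(qseq), _genome(contig)) == []

    def test_degenerate_positions_count_as_matches(self, rng):
        qseq = random_seq(rng, 270)
        contig, at = _plant(rng, qseq)
        degenerate = qseq[:100] + "N" * 4 + qseq[104:]
        hits = search(_query(degenerate), _genome(contig))
        assert len(hits) == 1
        assert hits[0].identity == 1.0

    def test_strand_invariance(self, rng):
        """Reverse-complementing the genome preserves plus-strand span sets."""
        qseq = random_seq(rng, 270)
        contig, at = _plant(rng, qseq, contig_len=20000)
        fwd = search(_query(qseq), _genome(contig))
        rev = search(_query(qseq), _genome(revcomp(contig)))
        L = len(contig)
        mirrored = sorted((L - h.end, L - h.start) for h in rev)
        assert sorted(h.span for h in fwd) == mirrored

    def test_determinism(self, rng):
        qseq = random_seq(rng, 270)
        contig, _ = _plant(rng, qseq, mutate=0.08)
        h1 = search(_query(qseq), _genome(contig))
        h2 = search(_query(qseq), _genome(contig))
        assert h1 == h2

    def test_tandem_copies_both_found(self, rng):
        qseq = random_seq(rng, 270)
        spacer = random_seq(rng, 150)
        contig = random_seq(rng, 3000) + qseq + spacer + qseq + random_seq(rng, 3000)
        hits = search(_query(qseq), _genome(contig))
        assert len(hits) == 2

    def test_word_size_longer_than_query_rejected(self, rng):
        q = _query(random_seq(rng, 120))
        with pytest.raises(ValueError):
            search(q, _genome(random_seq(rng, 1000)), SearchConfig(word_size=200))

    def test_agrees_with_full_smith_waterman_oracle(self, rng):
        """Windowed seeded extension equals a full-matrix local DP scan."""
        for trial in range(6):
            qseq = random_seq(rng, 250)
            positive = trial % 2 == 0
            if positive:
                contig, at = _plant(rng, qseq, contig_len=4000, mutate=0.08)
            else:
                contig = random_seq(rng, 4000)
            hits = search(_query(qseq), _genome(contig))
            oracle = sw_local_oracle(contig, qseq)
            config = SearchConfig()
            qualifies = (oracle is not None
                         and oracle[3] >= config.min_identity
                         and (oracle[2][1] - oracle[2][0]) / len(qseq)
                         >= config.min_query_coverage)
            if positive:
                assert qualifies and len(hits) == 1
                assert hits[0].score == pytest.approx(oracle[0])
                assert abs(hits[0].start - oracle[1][0]) <= 10
                assert abs(hits[0].end - oracle[1][1]) <= 10
            else:
                assert not qualifies
                assert hits == []


def _hit(start, end, identity, exon=2, cls="II", contig="c1", qid=None):
    return AlignmentHit(query_id=qid or f"{cls}_e{exon}_q{start}", contig_id=contig,
                        start=start, end=end, strand="+", identity=identity,
                        query_start=0, query_end=end - start, score=identity * 100,
                        mhc_class=cls, exon_label=exon)


class TestDedupe:
    def test_identical_spans_keep_higher_identity(self):
        kept = dedupe_hits([_hit(100, 400, 0.90), _hit(100, 400, 0.85)])
        assert len(kept) == 1
        assert kept[0].identity == 0.90

    def test_disjoint_spans_both_kept(self):
        assert len(dedupe_hits([_hit(100, 400, 0.9), _hit(1000, 1300, 0.9)])) == 2

    def test_distinct_exons_never_collapsed(self):
        hits = [_hit(100, 400, 0.9, exon=2), _hit(100, 400, 0.9, exon=3)]
        assert len(dedupe_hits(hits)) == 2

    def test_transitive_chain_single_survivor(self):
        """a~b~c overlapping chains collapse to the single best hit."""
        a = _hit(0, 100, 0.85)
        b = _hit(40, 140, 0.95)
        c = _hit(80, 180, 0.90)
        kept = dedupe_hits([a, b, c])
        comps = brute_overlap_components([(0, 100), (40, 140), (80, 180)])
        assert len(comps) == 1
        assert len(kept) == 1 and kept[0].identity == 0.95

    def test_matches_brute_force_components(self, rng):
        hits = []
        for _ in range(25):
            s = int(rng.integers(0, 3000))
            ln = int(rng.integers(100, 400))
            hits.append(_hit(s, s + ln, float(rng.uniform(0.75, 1.0))))
        kept = dedupe_hits(hits)
        comps = brute_overlap_components([h.span for h in hits])
        assert len(kept) == len(comps)
        expected = {max(comp, key=lambda i: (hits[i].identity, hits[i].score,
                                             -hits[i].start))
                    for comp in comps}
        assert {h.identity for h in kept} == {hits[i].identity for i in expected}
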