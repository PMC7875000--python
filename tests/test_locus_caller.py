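import numpy as np
import pytest

from mhcscan.alphabet import revcomp
from mhcscan.homology_search import dedupe_hits, search_all
from mhcscan.locus_caller import (LocusCallerConfig, call_loci, count_loci,
                                  detect_stop_codons, screen_pseudogenes)
from mhcscan.model import AlignmentHit, GenomeAssembly, LocusCall
from mhcscan.synthetic_data import SimulationConfig, simulate_genome, template_queries

from .conftest import random_seq
from .oracles import max_locus_chains


def _hit(start, end, exon, strand="+", cls="II", contig="c1"):
    return AlignmentHit(query_id=f"{cls}_e{exon}_q00", contig_id=contig,
                        start=start, end=end, strand=strand, identity=0.9,
                        query_start=0, query_end=end - start, score=100.0,
                        mhc_class=cls, exon_label=exon, frame_anchor=0)


class TestChaining:
    def test_three_exons_within_gap_form_one_locus(self):
        hits = [_hit(1000, 1270, 2), _hit(1500, 1770, 3), _hit(2100, 2380, 4)]
        loci, partials = call_loci(hits)
        assert len(loci) == 1 and partials == []
        assert loci[0].span == (1000, 2380)

    def test_excessive_gap_yields_partials(self):
        hits = [_hit(1000, 1270, 2), _hit(3900, 4170, 3), _hit(4300, 4570, 4)]
        loci, partials = call_loci(hits)
        assert loci == []
        assert partials and all(p.reason == "gap_exceeded" for p in partials)

    def test_gap_exactly_at_limit_inclusive(self):
        hits = [_hit(0, 270, 2), _hit(2270, 2540, 3), _hit(2600, 2870, 4)]
        loci, _ = call_loci(hits, LocusCallerConfig(max_gap=2000))
        assert len(loci) == 1

    def test_gap_one_over_limit_rejected(self):
        hits = [_hit(0, 270, 2), _hit(2271, 2541, 3), _hit(2600, 2870, 4)]
        loci, partials = call_loci(hits, LocusCallerConfig(max_gap=2000))
        assert loci == []

    def test_two_tandem_copies_assigned_separately(self):
        hits = []
        for base in (0, 10000):
            hits += [_hit(base, base + 270, 2), _hit(base + 500, base + 770, 3),
                     _hit(base + 1000, base + 1270, 4)]
        loci, partials = call_loci(hits)
        assert len(loci) == 2 and partials == []
        for locus, base in zip(loci, (0, 10000)):
            assert locus.exon_hits[2].start == base

    def test_minus_strand_gene_order(self):
        hits = [_hit(1000, 1270, 4, strand="-"), _hit(1500, 1770, 3, strand="-"),
                _hit(2100, 2380, 2, strand="-")]
        loci, partials = call_loci(hits)
        assert len(loci) == 1 and loci[0].strand == "-"

    def test_wrong_order_same_strand_not_called_when_colinear(self):
        hits = [_hit(1000, 1270, 3), _hit(1500, 1770, 2), _hit(2100, 2380, 4)]
        loci, partials = call_loci(hits, LocusCallerConfig(require_colinear_order=True))
        assert loci == []
        loci2, _ = call_loci(hits, LocusCallerConfig(require_colinear_order=False))
        assert len(loci2) == 1

    def test_missing_exon_reason(self):
        hits = [_hit(1000, 1270, 2), _hit(1500, 1770, 3)]
        loci, partials = call_loci(hits)
        assert loci == []
        assert [p.reason for p in partials] == ["missing_exon"]

    def test_unknown_contig_rejected(self, rng):
        genome = GenomeAssembly(assembly_id="g", contigs={"other": random_seq(rng, 100)})
        with pytest.raises(ValueError):
            call_loci([_hit(0, 50, 2)], genome=genome)

    def test_input_permutation_invariance(self, rng):
        hits = [_hit(0, 270, 2), _hit(500, 770, 3), _hit(1000, 1270, 4),
                _hit(5000, 5270, 2), _hit(5500, 5770, 3), _hit(6000, 6270, 4)]
        baseline, _ = call_loci(hits)
        for _ in range(5):
            perm = [hits[i] for i in rng.permutation(len(hits))]
            loci, _ = call_loci(perm)
            assert [l.span for l in loci] == [l.span for l in baseline]

    def test_max_gap_monotonicity(self, rng):
        hits = _random_hits(rng, 9)
        counts = [len(call_loci(hits, LocusCallerConfig(max_gap=g))[0])
                  for g in (500, 1000, 2000, 4000)]
        assert counts == sorted(counts)

    def test_greedy_matches_exhaustive_oracle(self, rng):
        """Greedy chaining attains the maximum chain count on random instances."""
        for _ in range(150):
            hits = _random_hits(rng, int(rng.integers(3, 10)))
            loci, _ = call_loci(hits)
            oracle = max_locus_chains(
                [(h.start, h.end, h.exon_label, h.strand) for h in hits],
                max_gap=2000)
            assert len(loci) == oracle


def _random_hits(rng, n, span=12000, strands="+-"):
    hits = []
    starts = sorted(int(rng.integers(0, span)) for _ in range(n))
    for s in starts:
        hits.append(_hit(s, s + int(rng.integers(100, 300)),
                         int(rng.choice([2, 3, 4])),
                         strand=str(rng.choice(list(strands)))))
    # drop overlapping spans to keep instances chainable
    out = []
    for h in sorted(hits, key=lambda h: h.start):
        if not out or h.start >= out[-1].end:
            out.append(h)
    return out


class TestStopCodons:
    def _locus_with_exon(self, rng, exon_seq, strand="+", cls="II"):
        """Build a genome holding one locus whose screening exon is exon_seq."""
        pre, mid1, mid2, post = (random_seq(rng, 1000), random_seq(rng, 300),
                                 random_seq(rng, 300), random_seq(rng, 1000))
        e3 = random_seq(rng, 270)
        e4 = random_seq(rng, 270)
        fwd = pre + exon_seq + mid1 + e3 + mid2 + e4 + post
        contig = fwd if strand == "+" else revcomp(fwd)
        L = len(fwd)

        def span(s, e):
            return (s, e) if strand == "+" else (L - e, L - s)

        spans = {2: span(1000, 1000 + len(exon_seq)),
                 3: span(1000 + len(exon_seq) + 300,
                         1000 + len(exon_seq) + 300 + 270),
                 4: span(1000 + len(exon_seq) + 870,
                         1000 + len(exon_seq) + 870 + 270)}
        hits = {e: AlignmentHit(query_id=f"{cls}_e{e}_q00", contig_id="c1",
                                start=spans[e][0], end=spans[e][1], strand=strand,
                                identity=1.0, query_start=0,
                                query_end=spans[e][1] - spans[e][0], score=100.0,
                                mhc_class=cls, exon_label=e, frame_anchor=0)
                for e in (2, 3, 4)}
        locus = LocusCall(locus_id="L1", contig_id="c1", mhc_class=cls,
                          strand=strand, exon_hits=hits)
        genome = GenomeAssembly(assembly_id="g", contigs={"c1": contig})
        return locus, genome

    def _coding_exon(self, rng, n_codons=90):
        codons = []
        while len(codons) < n_codons:
            c = random_seq(rng, 3)
            if c not in ("TAA", "TAG", "TGA"):
                codons.append(c)
        return "".join(codons)

    def test_planted_stop_detected_at_position(self, rng):
        exon = self._coding_exon(rng)
        exon = exon[:90] + "TGA" + exon[93:]  # codon 30 of 90
        locus, genome = self._locus_with_exon(rng, exon)
        flagged, positions = detect_stop_codons(locus, genome)
        assert flagged
        assert positions == [1000 + 90]
        assert locus.is_pseudogene

    def test_intact_exon_not_flagged(self, rng):
        locus, genome = self._locus_with_exon(rng, self._coding_exon(rng))
        flagged, positions = detect_stop_codons(locus, genome)
        assert (flagged, positions) == (False, [])

    def test_minus_strand_stop_detected(self, rng):
        exon = self._coding_exon(rng)
        exon = exon[:90] + "TAG" + exon[93:]
        locus, genome = self._locus_with_exon(rng, exon, strand="-")
        flagged, positions = detect_stop_codons(locus, genome)
        assert flagged and len(positions) == 1
        # position is the plus-strand offset of the codon
        s, e = locus.exon_hits[2].span
        assert s <= positions[0] <= e - 3

    def test_final_codon_stop_is_not_premature(self, rng):
        exon = self._coding_exon(rng)[:-3] + "TAA"
        locus, genome = self._locus_with_exon(rng, exon)
        assert detect_stop_codons(locus, genome) == (False, [])

    def test_simulated_pseudogenes_recovered_exactly(self):
        """End to end: flags recovered on a simulated genome match truth."""
        config = SimulationConfig(seed=77, n_class_I=4, n_class_II=6)
        assembly, truth = simulate_genome(config)
        hits = search_all(template_queries(config), assembly)
        loci, _ = call_loci(dedupe_hits(hits), genome=assembly)
        screen_pseudogenes(loci, assembly)
        assert len(loci) == len(truth)
        truth_by_key = {}
        for t in truth:
            truth_by_key[(t.contig_id, t.mhc_class, t.span[0] // 100)] = t
        for locus in loci:
            match = [t for t in truth
                     if t.contig_id == locus.contig_id
                     and t.mhc_class == locus.mhc_class
                     and max(0, min(t.span[1], locus.span[1])
                             - max(t.span[0], locus.span[0])) > 0]
            assert len(match) == 1
            t = match[0]
            assert locus.is_pseudogene == t.is_pseudogene
            if t.is_pseudogene:
                assert t.planted_stop_position in locus.stop_codon_positions


class TestCounting:
    def test_rendered_convention(self):
        from mhcscan.locus_caller import LocusSummary

        s = LocusSummary(n_loci={"I": 5, "II": 11}, n_pseudogene={"I": 2, "II": 0},
                         n_partial_clusters={"I": 0, "II": 0})
        assert s.rendered("II") == "11"
        assert s.rendered("I") == "5(2)"

    def test_partials_do_not_count_as_loci(self):
        hits = [_hit(1000, 1270, 2), _hit(3900, 4170, 3), _hit(4300, 4570, 4)]
        loci, partials = call_loci(hits)
        summary = count_loci(loci, partials)
        assert summary.n_loci == {"I": 0, "II": 0}
        assert summary.n_partial_clusters["II"] >= 1

    def test_empty_inputs_all_zero(self):
        summary = count_loci([], [])
        assert summary.n_loci == {"I": 0, "II": 0}
        assert summary.n_pseudogene == {"I": 0, "II": 0}
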