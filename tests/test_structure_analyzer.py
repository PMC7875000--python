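import numpy as np
import pytest

from mhcscan.alphabet import revcomp
from mhcscan.homology_search import dedupe_hits, search_all
from mhcscan.locus_caller import call_loci
from mhcscan.model import AlignmentHit, GenomeAssembly, LocusCall
from mhcscan.structure_analyzer import (DotplotConfig, classify_duplication,
                                        contig_class_composition, extract_flanks,
                                        find_duplicated_blocks, multilocus_contigs,
                                        self_dotplot)
from mhcscan.synthetic_data import SimulationConfig, simulate_genome, template_queries

from .conftest import random_seq


def _locus(contig, start, cls="II", pseudo=False):
    hits = {}
    pos = start
    for exon in (2, 3, 4):
        hits[exon] = AlignmentHit(query_id=f"{cls}_e{exon}_q00", contig_id=contig,
                                  start=pos, end=pos + 270, strand="+", identity=0.9,
                                  query_start=0, query_end=270, score=100.0,
                                  mhc_class=cls, exon_label=exon)
        pos += 500
    l = LocusCall(locus_id=f"{contig}:{cls}:{start}", contig_id=contig,
                  mhc_class=cls, strand="+", exon_hits=hits)
    l.is_pseudogene = pseudo
    return l


class TestMultilocusContigs:
    def test_single_locus_contig_excluded(self):
        assert multilocus_contigs([_locus("c1", 0)]) == []

    def test_two_locus_contig_included_with_composition(self):
        group = [_locus("c1", 0), _locus("c1", 5000)]
        out = multilocus_contigs(group)
        assert len(out) == 1
        contig_id, loci = out[0]
        assert contig_id == "c1" and len(loci) == 2
        assert contig_class_composition(loci) == "classII_only"

    def test_per_contig_counts(self):
        loci = ([_locus("a", i * 4000) for i in range(3)]
                + [_locus("b", 0)]
                + [_locus("c", i * 4000) for i in range(5)])
        out = multilocus_contigs(loci)
        assert [(cid, len(g)) for cid, g in out] == [("a", 3), ("c", 5)]

    def test_pseudogene_exclusion(self):
        loci = [_locus("c1", 0), _locus("c1", 5000, pseudo=True)]
        assert multilocus_contigs(loci, exclude_pseudogenes=True) == []


class TestSelfDotplot:
    def test_random_sequence_collision_rate(self, rng):
        """Chance word matches follow the 4^-k collision rate and stay
        scattered: no spurious duplication blocks arise from them."""
        config = DotplotConfig()
        seq = random_seq(rng, 10000)
        matches = self_dotplot(seq, config)
        direct = [m for m in matches if m[2] == "direct"]
        expected = (10000 ** 2 / 2) / 4 ** config.word_size  # ~48
        assert len(direct) < 4 * expected
        assert find_duplicated_blocks(matches, config) == []

    def test_tandem_repeat_full_offset_diagonal(self, rng):
        u = random_seq(rng, 3000)
        matches = self_dotplot(u + u, DotplotConfig())
        on_offset = [(i, j) for i, j, o in matches if o == "direct" and j - i == 3000]
        assert len(on_offset) >= 3000 - 10 - 5

    def test_palindromic_planting_detected_inverted(self, rng):
        u = random_seq(rng, 2000)
        seq = random_seq(rng, 1000) + u + random_seq(rng, 500) + revcomp(u) \
            + random_seq(rng, 1000)
        matches = self_dotplot(seq, DotplotConfig())
        inverted = [m for m in matches if m[2] == "inverted"]
        assert len(inverted) > 1500

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            self_dotplot("ACGTACGT", DotplotConfig())

    def test_canonical_i_less_than_j(self, rng):
        seq = random_seq(rng, 2000) * 2
        for i, j, _o in self_dotplot(seq, DotplotConfig()):
            assert i < j


class TestDuplicationBlocks:
    def test_planted_tandem_unit_recovered(self, rng):
        u = random_seq(rng, 5000)
        seq = random_seq(rng, 2000) + u + u + random_seq(rng, 2000)
        config = DotplotConfig()
        blocks = find_duplicated_blocks(self_dotplot(seq, config), config)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.orientation == "direct"
        assert abs(b.span_a[0] - 2000) <= 100 and abs(b.span_a[1] - 7000) <= 100
        assert abs(b.span_b[0] - 7000) <= 100 and abs(b.span_b[1] - 12000) <= 100

    def test_no_planting_no_blocks(self, rng):
        config = DotplotConfig()
        for _ in range(5):
            seq = random_seq(rng, 20000)
            assert find_duplicated_blocks(self_dotplot(seq, config), config) == []

    def test_diverged_copies_still_chained(self, rng):
        u = random_seq(rng, 5000)
        chars = list(u)
        for i in rng.choice(5000, size=250, replace=False):  # 5% divergence
            chars[i] = "ACGT"[rng.integers(4)]
        u2 = "".join(chars)
        seq = random_seq(rng, 2000) + u + u2 + random_seq(rng, 2000)
        config = DotplotConfig()
        blocks = find_duplicated_blocks(self_dotplot(seq, config), config)
        assert len(blocks) == 1 and blocks[0].length >= 4500

    def test_nested_duplication_containment(self, rng):
        """An extra copy of an inner 5 kb unit is seen at its own offset."""
        u5 = random_seq(rng, 5000)
        u12 = random_seq(rng, 3000) + u5 + random_seq(rng, 4000)
        seq = (random_seq(rng, 2000) + u12 + u12 + random_seq(rng, 1500)
               + u5 + random_seq(rng, 1500))
        config = DotplotConfig()
        blocks = find_duplicated_blocks(self_dotplot(seq, config), config)
        assert any(b.length >= 11500 for b in blocks)  # the 12 kb unit
        five_k = [b for b in blocks if 4500 <= b.length <= 5500]
        assert five_k  # the inner unit at its own offset

    def test_inverted_duplication_orientation(self, rng):
        u = random_seq(rng, 4000)
        seq = random_seq(rng, 2000) + u + random_seq(rng, 1000) + revcomp(u) \
            + random_seq(rng, 2000)
        config = DotplotConfig()
        blocks = find_duplicated_blocks(self_dotplot(seq, config), config)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"


class TestClassification:
    def _sim_blocks_and_loci(self, mode, seed):
        config = SimulationConfig(seed=seed, n_class_I=2, n_class_II=2,
                                  duplication_mode=mode, n_duplicate_copies=3)
        assembly, truth = simulate_genome(config)
        hits = search_all(template_queries(config), assembly)
        loci, _ = call_loci(dedupe_hits(hits), genome=assembly)
        dc = DotplotConfig()
        blocks = find_duplicated_blocks(self_dotplot(assembly.contigs["dup00"], dc),
                                        dc, contig_id="dup00")
        return blocks, loci

    def test_co_duplication_mode_classified(self):
        blocks, loci = self._sim_blocks_and_loci("co_duplication", seed=3)
        assert blocks
        patterns = {c.pattern for c in classify_duplication(blocks, loci)}
        assert patterns == {"co_duplication"}

    def test_tandem_class_ii_mode_classified(self):
        blocks, loci = self._sim_blocks_and_loci("tandem_classII", seed=4)
        assert blocks
        patterns = {c.pattern for c in classify_duplication(blocks, loci)}
        assert patterns == {"classII_only"}

    def test_block_without_loci_is_none(self, rng):
        from mhcscan.model import DuplicationBlock

        block = DuplicationBlock(contig_id="c9", span_a=(0, 3000),
                                 span_b=(5000, 8000), length=3000,
                                 orientation="direct")
        (cl,) = classify_duplication([block], [_locus("c1", 0)])
        assert cl.pattern == "none"


class TestFlanks:
    def _genome(self, rng, n=100000):
        return GenomeAssembly(assembly_id="g", contigs={"c1": random_seq(rng, n)})

    def test_interior_window(self, rng):
        genome = self._genome(rng)
        locus = _locus("c1", 12000)
        locus.exon_hits[4] = AlignmentHit(
            query_id="II_e4_q00", contig_id="c1", start=14730, end=15000,
            strand="+", identity=0.9, query_start=0, query_end=270, score=100.0,
            mhc_class="II", exon_label=4)
        lo, hi, seq = extract_flanks(locus, genome, flank=10000)
        assert (lo, hi) == (2000, 25000)
        assert len(seq) == 23000

    def test_start_clipping(self, rng):
        genome = self._genome(rng)
        locus = _locus("c1", 500)
        lo, hi, seq = extract_flanks(locus, genome, flank=10000)
        assert lo == 0
        assert hi == locus.span[1] + 10000

    def test_unclipped_length_identity(self, rng):
        genome = self._genome(rng)
        locus = _locus("c1", 30000)
        lo, hi, seq = extract_flanks(locus, genome, flank=10000)
        span = locus.span
        assert hi - lo == (span[1] - span[0]) + 20000
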