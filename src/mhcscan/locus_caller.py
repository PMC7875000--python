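"""Calling MHC loci from deduplicated exon hits.

The central rule: a locus is a run of hits for exons 2, 3 and 4 of one MHC
class on one contig, with every consecutive-exon gap (end of one hit to
start of the next) at most ``max_gap`` (2 kb by default, inclusive -- the
spacing of introns in annotated MHC genes).  Exons must appear in gene
order along one strand by default (2-3-4 on plus, encountered as 4-3-2 on
minus); both constraints are toggleable for sensitivity analysis.

Chaining is greedy left-to-right with backtracking: the leftmost unused
hit that can start a chain is extended by the nearest downstream hit of
the expected next label within the gap limit, trying further candidates
if the nearest one leads to a dead end.  Only complete chains consume
their hits.  Hits left over are grouped into partial clusters annotated
with the reason they could not be promoted.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

from .alphabet import STOP_CODONS, revcomp
from .model import (EXON_LABELS, SCREENING_EXON, AlignmentHit, GenomeAssembly,
                    LocusCall, PartialCluster)


@dataclass(frozen=True)
class LocusCallerConfig:
    max_gap: int = 2000
    require_colinear_order: bool = True
    require_same_strand: bool = True
    all_pairs_gap: bool = False  # stricter reading: every exon pair within max_gap

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")


@dataclass
class LocusSummary:
    """Per-class totals in the published table's total(n_stop) convention."""

    n_loci: dict[str, int]
    n_pseudogene: dict[str, int]
    n_partial_clusters: dict[str, int]

    def n_intact(self, mhc_class: str) -> int:
        return self.n_loci[mhc_class] - self.n_pseudogene[mhc_class]

    def rendered(self, mhc_class: str) -> str:
        """``total(n_stop)`` rendering, e.g. ``"11(0)"`` -> ``"11"``."""
        n, s = self.n_loci[mhc_class], self.n_pseudogene[mhc_class]
        return f"{n}({s})" if s else str(n)


def _chain_gap_ok(prev: AlignmentHit, nxt: AlignmentHit, max_gap: int) -> bool:
    gap = nxt.start - prev.end
    return 0 <= gap <= max_gap


def _complete_chain(start_hit: AlignmentHit, order: Sequence[int],
                    pool: list[AlignmentHit], used: set[int],
                    config: LocusCallerConfig) -> Optional[list[AlignmentHit]]:
    """Depth-first completion of a chain, nearest candidates first."""

    def extend(chain: list[AlignmentHit], labels_left: Sequence[int]):
        if not labels_left:
            if config.all_pairs_gap:
                for i in range(len(chain)):
                    for j in range(i + 1, len(chain)):
                        gap = chain[j].start - chain[i].end
                        if gap > config.max_gap:
                            return None
            return chain
        want = labels_left[0]
        prev = chain[-1]
        candidates = [h for idx, h in enumerate(pool)
                      if idx not in used and h not in chain
                      and h.exon_label == want
                      and _chain_gap_ok(prev, h, config.max_gap)]
        for cand in sorted(candidates, key=lambda h: h.start):
            result = extend(chain + [cand], labels_left[1:])
            if result is not None:
                return result
        return None

    if start_hit.exon_label != order[0]:
        return None
    return extend([start_hit], list(order[1:]))


def call_loci(hits: Sequence[AlignmentHit],
              config: LocusCallerConfig = LocusCallerConfig(),
              genome: Optional[GenomeAssembly] = None,
              ) -> tuple[list[LocusCall], list[PartialCluster]]:
    """Assemble deduplicated exon hits into locus calls and partial clusters."""
    if genome is not None:
        for h in hits:
            if h.contig_id not in genome.contigs:
                raise ValueError(f"hit references unknown contig {h.contig_id}")
            if h.end > len(genome.contigs[h.contig_id]):
                raise ValueError(f"hit extends past end of contig {h.contig_id}")
    for h in hits:
        if h.exon_label not in EXON_LABELS or h.mhc_class is None:
            raise ValueError(f"hit {h.query_id} lacks class/exon annotation")

    loci: list[LocusCall] = []
    leftovers: list[AlignmentHit] = []
    groups: dict[tuple, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        key = (h.contig_id, h.mhc_class) + ((h.strand,) if config.require_same_strand else ())
        groups[key].append(h)

    counter: dict[str, int] = defaultdict(int)
    for key in sorted(groups):
        contig_id, mhc_class = key[0], key[1]
        pool = sorted(groups[key], key=lambda h: (h.start, h.exon_label))
        used: set[int] = set()
        for i, h in enumerate(pool):
            if i in used:
                continue
            if config.require_colinear_order:
                if config.require_same_strand:
                    orders = ((2, 3, 4),) if h.strand == "+" else ((4, 3, 2),)
                else:
                    orders = ((2, 3, 4), (4, 3, 2))
                chain = None
                for order in orders:
                    chain = _complete_chain(h, order, pool, used, config)
                    if chain is not None:
                        break
            else:
                chain = None
                for order in ((2, 3, 4), (2, 4, 3), (3, 2, 4), (3, 4, 2),
                              (4, 2, 3), (4, 3, 2)):
                    chain = _complete_chain(h, order, pool, used, config)
                    if chain is not None:
                        break
            if chain is not None:
                for c in chain:
                    used.add(pool.index(c))
                counter[mhc_class] += 1
                locus_strand = chain[0].strand
                loci.append(LocusCall(
                    locus_id=f"{contig_id}:{mhc_class}:L{counter[mhc_class]:03d}",
                    contig_id=contig_id, mhc_class=mhc_class,
                    strand=locus_strand,
                    exon_hits={c.exon_label: c for c in chain},
                ))
        leftovers.extend(h for i, h in enumerate(pool) if i not in used)

    partials = _group_partials(leftovers, hits, config)
    return sorted(loci, key=lambda l: (l.contig_id, l.span[0])), partials


def _group_partials(leftovers: list[AlignmentHit], all_hits: Sequence[AlignmentHit],
                    config: LocusCallerConfig) -> list[PartialCluster]:
    """Group leftover hits by proximity and diagnose why each group failed."""
    partials: list[PartialCluster] = []
    by_cc: dict[tuple, list[AlignmentHit]] = defaultdict(list)
    for h in leftovers:
        by_cc[(h.contig_id, h.mhc_class)].append(h)
    for (contig_id, mhc_class), grp in sorted(by_cc.items()):
        grp = sorted(grp, key=lambda h: h.start)
        contig_labels = {h.exon_label for h in all_hits
                         if h.contig_id == contig_id and h.mhc_class == mhc_class}
        cluster: list[AlignmentHit] = []
        for h in grp:
            if cluster and h.start - cluster[-1].end > config.max_gap:
                partials.append(_diagnose(contig_id, mhc_class, cluster,
                                          contig_labels, config))
                cluster = []
            cluster.append(h)
        if cluster:
            partials.append(_diagnose(contig_id, mhc_class, cluster,
                                      contig_labels, config))
    return partials


def _diagnose(contig_id: str, mhc_class: str, cluster: list[AlignmentHit],
              contig_labels: set, config: LocusCallerConfig) -> PartialCluster:
    labels = {h.exon_label for h in cluster}
    strands = {h.strand for h in cluster}
    if labels == set(EXON_LABELS) and len(strands) > 1 and config.require_same_strand:
        reason = "strand_conflict"
    elif contig_labels == set(EXON_LABELS) and labels != set(EXON_LABELS):
        # the missing exon exists on this contig, just too far away
        reason = "gap_exceeded"
    elif labels != set(EXON_LABELS):
        reason = "missing_exon"
    else:
        reason = "gap_exceeded"
    return PartialCluster(contig_id=contig_id, mhc_class=mhc_class,
                         hits=cluster, reason=reason)


# ---------------------------------------------------------------------------
# pseudogene screening
# ---------------------------------------------------------------------------

def detect_stop_codons(locus: LocusCall, genome: GenomeAssembly,
                       ) -> tuple[bool, list[int]]:
    """Screen the peptide-binding exon of a locus for premature stop codons.

    The screening exon (3 for class I, 2 for class II) is located by its
    hit; since a local alignment may trim mismatch-rich exon ends, the
    extracted window is extended by the unaligned query prefix/suffix (when
    the hit carries the query length) so the whole exon is screened.  The
    window is reverse-complemented for minus-strand loci and translated in
    the frame implied by the hit's query coordinates.  TAA/TAG/TGA before
    the final codon flag the locus as a pseudogene; returned positions are
    plus-strand contig offsets of the offending codons.  Frameshifts are
    deliberately not screened; only stop codons count here.
    """
    exon = SCREENING_EXON[locus.mhc_class]
    hit = locus.exon_hits.get(exon)
    if hit is None:
        raise ValueError(f"locus {locus.locus_id} lacks its screening exon {exon}")
    contig = genome.contigs.get(locus.contig_id)
    if contig is None:
        raise ValueError(f"unknown contig {locus.contig_id}")

    qlen = hit.query_length if hit.query_length else hit.query_end
    left_ext = hit.query_start          # query bases trimmed before the alignment
    right_ext = max(0, qlen - hit.query_end)
    if hit.strand == "+":
        lo = max(0, hit.start - left_ext)
        hi = min(len(contig), hit.end + right_ext)
        lead = hit.start - lo           # left extension actually recovered
    else:
        lo = max(0, hit.start - right_ext)
        hi = min(len(contig), hit.end + left_ext)
        lead = hi - hit.end
    window = contig[lo:hi]
    if hit.strand == "-":
        window = revcomp(window)
    if len(window) < 9:
        raise ValueError("screening exon shorter than 3 codons")

    # Reading frame: anchor on the *dominant* (longest) gap-free run of the
    # alignment.  Micro-indels in a local alignment are usually either end
    # artefacts or net-zero shuffles that dodge a mismatch triplet (a stop
    # codon is exactly such a triplet), so the longest run's query/subject
    # register is the trustworthy frame for the whole exon window.
    runs = hit.blocks
    if not runs:
        runs = ((hit.query_start, 0, hit.query_end - hit.query_start),)
    q_off, s_off, _length = max(runs, key=lambda r: r[2])
    register = s_off - q_off  # window offset of query position 0 minus lead

    positions: list[int] = []
    for j in range(qlen // 3 - 1):  # premature only: final query codon excluded
        w = lead + register + 3 * j
        if w < 0 or w + 3 > len(window):
            continue
        codon = window[w : w + 3]
        if codon in STOP_CODONS:
            if hit.strand == "+":
                positions.append(lo + w)
            else:
                positions.append(hi - w - 3)
    flagged = bool(positions)
    locus.is_pseudogene = flagged
    locus.stop_codon_positions = sorted(positions)
    return flagged, sorted(positions)


def screen_pseudogenes(loci: Sequence[LocusCall], genome: GenomeAssembly) -> None:
    """Run stop-codon screening on every locus in place."""
    for locus in loci:
        detect_stop_codons(locus, genome)


def count_loci(loci: Sequence[LocusCall],
               partials: Sequence[PartialCluster] = ()) -> LocusSummary:
    """Per-class totals; pseudogenes reported separately (``total(n_stop)``)."""
    n = {"I": 0, "II": 0}
    n_pseudo = {"I": 0, "II": 0}
    n_partial = {"I": 0, "II": 0}
    for locus in loci:
        n[locus.mhc_class] += 1
        if locus.is_pseudogene:
            n_pseudo[locus.mhc_class] += 1
    for p in partials:
        n_partial[p.mhc_class] += 1
    return LocusSummary(n_loci=n, n_pseudogene=n_pseudo, n_partial_clusters=n_partial)
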