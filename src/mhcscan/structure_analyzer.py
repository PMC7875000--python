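"""MHC architecture: multilocus contigs, self-dotplot duplication blocks,
co-duplication classification, and flank extraction.

The self-dotplot is a word-match plot of a contig against itself: runs of
matching words on a common off-diagonal reveal duplicated blocks (direct
orientation on constant ``j - i``, inverted on constant ``i + j``).
Divergence between duplicated copies breaks the exact-word runs, so block
detection chains matches tolerating bounded jitter in the diagonal and
bounded gaps along it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .alphabet import revcomp
from .model import (DuplicationBlock, DuplicationUnitClassification,
                    GenomeAssembly, LocusCall)


@dataclass(frozen=True)
class DotplotConfig:
    word_size: int = 10
    min_block_length: int = 2000
    max_diag_jitter: int = 50
    chain_gap: int = 200          # max run gap along a diagonal
    max_word_occurrences: int = 100  # skip hyper-repetitive words

    def __post_init__(self) -> None:
        if self.word_size < 6:
            raise ValueError("word_size must be >= 6")
        if self.min_block_length <= self.word_size:
            raise ValueError("min_block_length must exceed word_size")


# ---------------------------------------------------------------------------
# multilocus contigs
# ---------------------------------------------------------------------------

def multilocus_contigs(loci: Sequence[LocusCall], exclude_pseudogenes: bool = False,
                       ) -> list[tuple[str, list[LocusCall]]]:
    """Contigs carrying two or more called loci, loci sorted by position."""
    pool = [l for l in loci if not (exclude_pseudogenes and l.is_pseudogene)]
    by_contig: dict[str, list[LocusCall]] = defaultdict(list)
    for l in pool:
        by_contig[l.contig_id].append(l)
    out = []
    for contig_id in sorted(by_contig):
        group = sorted(by_contig[contig_id], key=lambda l: l.span[0])
        if len(group) >= 2:
            out.append((contig_id, group))
    return out


def contig_class_composition(loci: Sequence[LocusCall]) -> str:
    classes = {l.mhc_class for l in loci}
    if classes == {"I", "II"}:
        return "both_classes"
    if classes == {"I"}:
        return "classI_only"
    if classes == {"II"}:
        return "classII_only"
    return "none"


# ---------------------------------------------------------------------------
# self-dotplot
# ---------------------------------------------------------------------------

def self_dotplot(sequence: str, config: DotplotConfig = DotplotConfig(),
                 ) -> set[tuple[int, int, str]]:
    """All off-diagonal word matches (i, j, orientation) with i < j.

    Direct matches: word at i equals word at j.  Inverted: word at i equals
    the reverse complement of the word at j.  The main diagonal (and the
    centre of word-level palindromes) is excluded.
    """
    k = config.word_size
    if len(sequence) < 2 * k:
        raise ValueError("sequence shorter than two words")
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sequence) - k + 1):
        index[sequence[i : i + k]].append(i)
    matches: set[tuple[int, int, str]] = set()
    for word, positions in index.items():
        if len(positions) > config.max_word_occurrences:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                matches.add((positions[a], positions[b], "direct"))
        rc = revcomp(word)
        if rc in index and len(index[rc]) <= config.max_word_occurrences:
            for i in positions:
                for j in index[rc]:
                    if i < j:
                        matches.add((i, j, "inverted"))
    return matches


def find_duplicated_blocks(matches: Iterable[tuple[int, int, str]],
                           config: DotplotConfig = DotplotConfig(),
                           contig_id: str = "contig",
                           ) -> list[DuplicationBlock]:
    """Chain collinear word matches into duplication blocks.

    Direct matches sharing an off-diagonal (``j - i`` within
    ``max_diag_jitter``) and spaced at most ``chain_gap`` apart along it are
    merged; likewise inverted matches on a common anti-diagonal (``i + j``).
    Blocks of at least ``min_block_length`` are reported, longest first.
    """
    w = config.word_size
    blocks: list[DuplicationBlock] = []
    for orientation in ("direct", "inverted"):
        pts = [(i, j) for (i, j, o) in matches if o == orientation]
        if not pts:
            continue
        keyfun = (lambda p: p[1] - p[0]) if orientation == "direct" else (lambda p: p[0] + p[1])
        # first split into diagonal bands: matches separated by more than the
        # jitter in (anti)diagonal belong to different duplication offsets
        pts.sort(key=keyfun)
        bands: list[list[tuple[int, int]]] = [[pts[0]]]
        for p in pts[1:]:
            if keyfun(p) - keyfun(bands[-1][-1]) > config.max_diag_jitter:
                bands.append([])
            bands[-1].append(p)
        # then chain along each band; gaps over chain_gap split the run
        for band in bands:
            band.sort()
            chain: list[tuple[int, int]] = []
            for p in band + [(None, None)]:
                if chain and (p[0] is None or p[0] - chain[-1][0] > config.chain_gap):
                    block = _chain_to_block(chain, w, config, contig_id, orientation)
                    if block is not None:
                        blocks.append(block)
                    chain = []
                if p[0] is not None:
                    chain.append(p)
    return sorted(blocks, key=lambda b: -b.length)


def _chain_to_block(chain: list[tuple[int, int]], w: int, config: DotplotConfig,
                    contig_id: str, orientation: str) -> DuplicationBlock | None:
    i_lo = min(p[0] for p in chain)
    i_hi = max(p[0] for p in chain) + w
    j_lo = min(p[1] for p in chain)
    j_hi = max(p[1] for p in chain) + w
    length = max(i_hi - i_lo, j_hi - j_lo)
    span_a, span_b = sorted([(i_lo, i_hi), (j_lo, j_hi)])
    if length < config.min_block_length or span_a == span_b:
        return None
    return DuplicationBlock(contig_id=contig_id, span_a=span_a, span_b=span_b,
                            length=length, orientation=orientation)


# ---------------------------------------------------------------------------
# duplication-unit classification
# ---------------------------------------------------------------------------

def _loci_in_span(span: tuple[int, int], loci: Sequence[LocusCall],
                  min_containment: float = 0.8) -> list[LocusCall]:
    out = []
    for l in loci:
        s, e = l.span
        ov = max(0, min(e, span[1]) - max(s, span[0]))
        if ov >= min_containment * (e - s):
            out.append(l)
    return out


def classify_duplication(blocks: Sequence[DuplicationBlock],
                         loci: Sequence[LocusCall],
                         ) -> list[DuplicationUnitClassification]:
    """Classify each duplication block by the locus classes its two copies share.

    Co-duplication requires at least one class I and one class II locus
    inside each of the block's two spans; a block whose copies share only
    one class is a class-specific duplication; a block overlapping no loci
    is ``none``.
    """
    out = []
    for block in blocks:
        by_contig = [l for l in loci if l.contig_id == block.contig_id]
        in_a = _loci_in_span(block.span_a, by_contig)
        in_b = _loci_in_span(block.span_b, by_contig)
        classes_a = {l.mhc_class for l in in_a}
        classes_b = {l.mhc_class for l in in_b}
        shared = classes_a & classes_b
        if shared == {"I", "II"}:
            pattern = "co_duplication"
        elif shared == {"I"}:
            pattern = "classI_only"
        elif shared == {"II"}:
            pattern = "classII_only"
        else:
            pattern = "none"
        out.append(DuplicationUnitClassification(
            contig_id=block.contig_id, pattern=pattern,
            participating_loci=sorted(l.locus_id for l in in_a + in_b)))
    return out


# ---------------------------------------------------------------------------
# flank extraction and arrangement export
# ---------------------------------------------------------------------------

def extract_flanks(locus: LocusCall, genome: GenomeAssembly, flank: int = 10000,
                   ) -> tuple[int, int, str]:
    """Sequence window around a locus, 10 kb each side, clipped to the contig.

    Returns (window_start, window_end, sequence); intended as input to an
    external gene annotator.
    """
    contig = genome.contigs.get(locus.contig_id)
    if contig is None:
        raise ValueError(f"unknown contig {locus.contig_id}")
    start, end = locus.span
    lo = max(0, start - flank)
    hi = min(len(contig), end + flank)
    return lo, hi, contig[lo:hi]


def write_arrangement_tsv(loci: Sequence[LocusCall], path: str | Path) -> None:
    """Plot-ready table of locus arrangement (one row per locus)."""
    with open(path, "w") as fh:
        fh.write("contig_id\tlocus_id\tmhc_class\tstart\tend\tstrand\tpseudogene\n")
        for l in sorted(loci, key=lambda l: (l.contig_id, l.span[0])):
            s, e = l.span
            fh.write(f"{l.contig_id}\t{l.locus_id}\t{l.mhc_class}\t{s}\t{e}\t"
                     f"{l.strand}\t{'true' if l.is_pseudogene else 'false'}\n")
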