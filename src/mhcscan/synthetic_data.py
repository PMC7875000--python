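"""Synthetic genomes and exon corpora with planted ground truth.

The generator emulates the statistical structure the scan assumes: loci of
three exons separated by introns short enough for the 2 kb chaining rule,
separated by long intergenic spacers; per-base divergence between the
planted copies and the search templates; a configurable fraction of
pseudogenes carrying one forced in-frame stop codon in the peptide-binding
exon; optional tandem or class-I+II cassette duplication; and optional
short-fragment ("NGS-like") contig fragmentation that splits loci across
contig breaks, reproducing the undercounting seen in short-read
assemblies.  Every quantity flows from one seeded generator, so a config
plus seed reproduces the FASTA byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .alphabet import STOP_CODONS, revcomp
from .model import (SCREENING_EXON, ConsensusQuery, ExonSeqRecord,
                    GenomeAssembly, TruthRecord)

DEFAULT_EXON_LENGTHS = {
    "I": {2: 270, 3: 276, 4: 276},
    "II": {2: 270, 3: 282, 4: 261},
}

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated genome."""

    seed: int = 1
    n_class_I: int = 5
    n_class_II: int = 13
    exon_lengths: dict = field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_EXON_LENGTHS.items()})
    intron_length_range: tuple[int, int] = (200, 1800)
    divergence: float = 0.08
    pseudogene_fraction: float = 0.2
    duplication_mode: str = "none"  # none | tandem_classII | co_duplication
    n_duplicate_copies: int = 3
    duplication_copy_divergence: float = 0.02
    intergenic_length_range: tuple[int, int] = (5000, 20000)
    fragmentation: str = "tgs_like"  # tgs_like | ngs_like
    fragment_length_range: tuple[int, int] = (1000, 8000)
    gc_content: float = 0.45
    loci_per_contig: int = 5
    indel_rate: float = 0.0  # optional indel mode; excluded from exact recovery

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be within [0, 0.3]")
        if not 0 <= self.pseudogene_fraction <= 1:
            raise ValueError("pseudogene_fraction must be within [0, 1]")
        if self.duplication_mode not in ("none", "tandem_classII", "co_duplication"):
            raise ValueError(f"unknown duplication_mode {self.duplication_mode!r}")
        if self.fragmentation not in ("tgs_like", "ngs_like"):
            raise ValueError(f"unknown fragmentation {self.fragmentation!r}")
        if self.n_class_I < 0 or self.n_class_II < 0:
            raise ValueError("locus counts must be non-negative")
        if self.intron_length_range[1] > 2000:
            warnings.warn("intron lengths above 2 kb make planted loci uncallable "
                          "under the default chaining rule", stacklevel=2)


# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _strip_stops(seq: str, rng: np.random.Generator, gc: float) -> str:
    """Replace every frame-0 stop codon until the sequence is stop-free."""
    chars = list(seq)
    for i in range(0, len(chars) - len(chars) % 3, 3):
        while "".join(chars[i : i + 3]) in STOP_CODONS:
            chars[i : i + 3] = list(_random_seq(rng, 3, gc))
    return "".join(chars)


def _mutate(seq: str, rng: np.random.Generator, rate: float,
            forbid_frame0_stops: bool = False, gc: float = 0.45) -> str:
    """Per-base substitution at the given rate (i.i.d.)."""
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    out = "".join(chars)
    if forbid_frame0_stops:
        out = _strip_stops(out, rng, gc)
    return out


def _apply_indels(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    out: list[str] = []
    i = 0
    while i < len(seq):
        if rng.random() < rate:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                i += length  # deletion
                continue
            out.append(_random_seq(rng, length, 0.5))  # insertion
        out.append(seq[i])
        i += 1
    return "".join(out)


def make_template_exons(config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None,
                        ) -> dict[tuple[str, int], str]:
    """Per-class, per-exon random coding templates, stop-free in frame 0."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    templates = {}
    for mhc_class in ("I", "II"):
        for exon, length in sorted(config.exon_lengths[mhc_class].items()):
            seq = _random_seq(rng, length, config.gc_content)
            templates[(mhc_class, exon)] = _strip_stops(seq, rng, config.gc_content)
    return templates


def template_queries(config: SimulationConfig,
                     templates: Optional[dict] = None) -> list[ConsensusQuery]:
    """The class templates packaged as search queries (ground-truth probes)."""
    if templates is None:
        templates = make_template_exons(config)
    return [
        ConsensusQuery(query_id=f"{cls}_e{exon}_tmpl", level="global",
                       mhc_class=cls, exon_label=exon, sequence=seq)
        for (cls, exon), seq in sorted(templates.items())
    ]


# ---------------------------------------------------------------------------
# locus and genome construction
# ---------------------------------------------------------------------------

def _build_locus(mhc_class: str, templates: dict, config: SimulationConfig,
                 rng: np.random.Generator, pseudo: bool,
                 ) -> tuple[str, dict[int, tuple[int, int]], str, Optional[int]]:
    """One locus cassette.

    Returns (sequence, exon spans in cassette plus-strand coordinates,
    strand, plus-strand position of the planted stop codon or None).
    """
    gc = config.gc_content
    screen = SCREENING_EXON[mhc_class]
    exon_seqs: dict[int, str] = {}
    for exon in (2, 3, 4):
        seq = _mutate(templates[(mhc_class, exon)], rng, config.divergence,
                      forbid_frame0_stops=(exon == screen), gc=gc)
        if config.indel_rate > 0:
            seq = _apply_indels(seq, rng, config.indel_rate)
        exon_seqs[exon] = seq
    stop_local: Optional[int] = None
    if pseudo:
        seq = exon_seqs[screen]
        n_codons = len(seq) // 3
        codon = int(rng.integers(1, n_codons - 1))  # internal codon
        stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
        exon_seqs[screen] = seq[: 3 * codon] + stop + seq[3 * codon + 3 :]
        stop_local = 3 * codon

    lo, hi = config.intron_length_range
    introns = [_random_seq(rng, int(rng.integers(lo, hi + 1)), gc) for _ in range(2)]
    parts = [exon_seqs[2], introns[0], exon_seqs[3], introns[1], exon_seqs[4]]
    fwd = "".join(parts)
    spans_fwd: dict[int, tuple[int, int]] = {}
    off = 0
    for exon, part in zip((2, None, 3, None, 4), parts):
        if exon is not None:
            spans_fwd[exon] = (off, off + len(part))
        off += len(part)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        seq_out, spans = fwd, spans_fwd
        stop_pos = (spans_fwd[screen][0] + stop_local) if stop_local is not None else None
    else:
        L = len(fwd)
        seq_out = revcomp(fwd)
        spans = {e: (L - e2, L - s2) for e, (s2, e2) in spans_fwd.items()}
        stop_pos = (L - (spans_fwd[screen][0] + stop_local) - 3) \
            if stop_local is not None else None
    return seq_out, spans, strand, stop_pos


def simulate_genome(config: SimulationConfig,
                    ) -> tuple[GenomeAssembly, list[TruthRecord]]:
    """Plant MHC-like loci in random contigs and return assembly plus truth."""
    rng = np.random.default_rng(config.seed)
    templates = make_template_exons(config, rng)
    gc = config.gc_content
    lo_ig, hi_ig = config.intergenic_length_range

    classes = ["I"] * config.n_class_I + ["II"] * config.n_class_II
    order = rng.permutation(len(classes))
    classes = [classes[i] for i in order]

    # deterministic pseudogene counts per class (rounded), seeded choice of which
    pseudo_flags = [False] * len(classes)
    for mhc_class in ("I", "II"):
        idxs = [i for i, c in enumerate(classes) if c == mhc_class]
        k = int(round(config.pseudogene_fraction * len(idxs)))
        for i in rng.choice(idxs, size=k, replace=False) if k else []:
            pseudo_flags[int(i)] = True

    contigs: dict[str, str] = {}
    truth: list[TruthRecord] = []
    n_contigs = max(1, -(-len(classes) // config.loci_per_contig))
    chunks = [classes[i::n_contigs] for i in range(n_contigs)]
    flag_chunks = [pseudo_flags[i::n_contigs] for i in range(n_contigs)]

    locus_no = 0
    for ci, (chunk, flags) in enumerate(zip(chunks, flag_chunks)):
        contig_id = f"contig{ci:02d}"
        parts: list[str] = [_random_seq(rng, int(rng.integers(lo_ig, hi_ig + 1)), gc)]
        offset = len(parts[0])
        for mhc_class, pseudo in zip(chunk, flags):
            seq, spans, strand, stop_pos = _build_locus(
                mhc_class, templates, config, rng, pseudo)
            locus_no += 1
            truth.append(TruthRecord(
                locus_id=f"truth{locus_no:03d}", contig_id=contig_id,
                mhc_class=mhc_class,
                exon_spans={e: (s + offset, x + offset) for e, (s, x) in spans.items()},
                strand=strand, is_pseudogene=pseudo,
                planted_stop_position=(stop_pos + offset) if stop_pos is not None else None,
            ))
            parts.append(seq)
            offset += len(seq)
            spacer = _random_seq(rng, int(rng.integers(lo_ig, hi_ig + 1)), gc)
            parts.append(spacer)
            offset += len(spacer)
        contigs[contig_id] = "".join(parts)

    if config.duplication_mode != "none":
        dup_contig, dup_truth = _build_duplication_contig(
            templates, config, rng, start_no=locus_no)
        contigs["dup00"] = dup_contig
        truth.extend(dup_truth)

    assembly = GenomeAssembly(assembly_id=f"sim_seed{config.seed}",
                              contigs=contigs, technology_tag="synthetic")
    if config.fragmentation == "ngs_like":
        assembly, breakpoints = fragment_assembly(
            assembly, config.fragment_length_range, rng)
        truth = remap_truth(truth, breakpoints)
    return assembly, truth


def _build_duplication_contig(templates: dict, config: SimulationConfig,
                              rng: np.random.Generator, start_no: int,
                              ) -> tuple[str, list[TruthRecord]]:
    """A contig holding n_duplicate_copies of a duplication unit.

    The unit is one class II locus (tandem_classII) or a class I + class II
    cassette (co_duplication); copies diverge from the blueprint at
    ``duplication_copy_divergence`` outside the planted exons, and each
    copy's loci are rebuilt from the same seeds so exon content stays
    near-identical between copies.
    """
    gc = config.gc_content
    unit_classes = ["II"] if config.duplication_mode == "tandem_classII" else ["I", "II"]
    # freeze per-locus build seeds so all copies share exon/intron content
    build_seeds = [int(rng.integers(2**31)) for _ in unit_classes]
    spacer_seed = int(rng.integers(2**31))
    spacer_len = 1000

    parts: list[str] = [_random_seq(rng, 4000, gc)]
    offset = len(parts[0])
    truth: list[TruthRecord] = []
    locus_no = start_no
    for copy in range(config.n_duplicate_copies):
        for mhc_class, bseed in zip(unit_classes, build_seeds):
            brng = np.random.default_rng(bseed)
            seq, spans, strand, _stop = _build_locus(
                mhc_class, templates, config, brng, pseudo=False)
            if copy > 0:
                seq = _mutate(seq, rng, config.duplication_copy_divergence)
            locus_no += 1
            truth.append(TruthRecord(
                locus_id=f"truth{locus_no:03d}", contig_id="dup00",
                mhc_class=mhc_class,
                exon_spans={e: (s + offset, x + offset) for e, (s, x) in spans.items()},
                strand=strand, is_pseudogene=False,
                duplication_unit_id=f"unit{copy:02d}",
            ))
            parts.append(seq)
            offset += len(seq)
            srng = np.random.default_rng(spacer_seed)
            spacer = _random_seq(srng, spacer_len, gc)
            if copy > 0:
                spacer = _mutate(spacer, rng, config.duplication_copy_divergence)
            parts.append(spacer)
            offset += len(spacer)
    parts.append(_random_seq(rng, 4000, gc))
    return "".join(parts), truth


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def fragment_assembly(assembly: GenomeAssembly,
                      fragment_length_range: tuple[int, int],
                      rng: np.random.Generator,
                      ) -> tuple[GenomeAssembly, dict[str, list[int]]]:
    """Split every contig into short fragments (NGS-like contiguity).

    Returns the fragmented assembly and, per original contig, the sorted
    breakpoint offsets (fragment boundaries, excluding 0 and the end).
    """
    lo, hi = fragment_length_range
    contigs: dict[str, str] = {}
    breakpoints: dict[str, list[int]] = {}
    for contig_id, seq in assembly.contigs.items():
        cuts: list[int] = []
        pos = 0
        while True:
            pos += int(rng.integers(lo, hi + 1))
            if pos >= len(seq):
                break
            cuts.append(pos)
        breakpoints[contig_id] = cuts
        bounds = [0] + cuts + [len(seq)]
        for fi, (s, e) in enumerate(zip(bounds, bounds[1:])):
            contigs[f"{contig_id}_f{fi:03d}"] = seq[s:e]
    return (GenomeAssembly(assembly_id=assembly.assembly_id + "_ngs",
                           contigs=contigs, technology_tag=assembly.technology_tag),
            breakpoints)


def remap_truth(truth: Sequence[TruthRecord],
                breakpoints: dict[str, list[int]]) -> list[TruthRecord]:
    """Remap truth records onto fragments; loci straddling a cut are flagged."""
    out: list[TruthRecord] = []
    for rec in truth:
        cuts = breakpoints.get(rec.contig_id, [])
        bounds = [0] + list(cuts)
        span = rec.span
        frag_idx = max(i for i, b in enumerate(bounds) if b <= span[0])
        frag_start = bounds[frag_idx]
        frag_end = cuts[frag_idx] if frag_idx < len(cuts) else None
        intact = frag_end is None or span[1] <= frag_end
        frag_id = f"{rec.contig_id}_f{frag_idx:03d}"
        if intact:
            out.append(replace(
                rec, contig_id=frag_id,
                exon_spans={e: (s - frag_start, x - frag_start)
                            for e, (s, x) in rec.exon_spans.items()},
                planted_stop_position=(rec.planted_stop_position - frag_start
                                       if rec.planted_stop_position is not None else None),
            ))
        else:
            out.append(replace(rec, contig_id=frag_id, exon_spans={},
                               planted_stop_position=None, is_split=True))
    return out


def split_locus_count(truth: Sequence[TruthRecord]) -> int:
    return sum(1 for r in truth if r.is_split)


# ---------------------------------------------------------------------------
# hierarchical exon corpus
# ---------------------------------------------------------------------------

def make_exon_corpus(n_orders: int = 3, n_species_per_order: int = 2,
                     n_seqs_per_species: int = 5,
                     within_species_div: float = 0.03,
                     within_order_div: float = 0.12,
                     between_order_div: float = 0.45,
                     seed: int = 1, mhc_class: str = "II", exon_label: int = 2,
                     exon_length: int = 270, gc_content: float = 0.45,
                     ) -> list[ExonSeqRecord]:
    """A hierarchical radiation of exon sequences with controlled divergence.

    ``within_species_div`` and ``within_order_div`` are target *pairwise*
    divergences inside a species and between species of one order (children
    are mutated at half the rate from the common ancestor).
    ``between_order_div`` is the per-lineage divergence of each order
    ancestor from the root, so between-order identity saturates well below
    1 - within_order_div and deep clusters stay separable.
    """
    if not within_species_div < within_order_div < between_order_div:
        raise ValueError("divergences must be ordered: species < order < between-order")
    rng = np.random.default_rng(seed)
    root = _strip_stops(_random_seq(rng, exon_length, gc_content), rng, gc_content)
    records: list[ExonSeqRecord] = []
    for o in range(n_orders):
        order_anc = _mutate(root, rng, between_order_div)
        for s in range(n_species_per_order):
            species_anc = _mutate(order_anc, rng, within_order_div / 2)
            for q in range(n_seqs_per_species):
                seq = _mutate(species_anc, rng, within_species_div / 2)
                records.append(ExonSeqRecord(
                    seq_id=f"o{o}_s{s}_{q:02d}",
                    species=f"order{o}_species{s}",
                    order_name=f"order{o}",
                    mhc_class=mhc_class, exon_label=exon_label,
                    sequence=seq,
                ))
    return records
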