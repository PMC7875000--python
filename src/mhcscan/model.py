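"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open on the plus strand throughout, with an
explicit strand flag; the on-disk formats (GFF3, 12-column hit tables) use
their own 1-based conventions and are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .alphabet import GENOME_ALPHABET, IUPAC_ALPHABET, degeneracy_fraction, validate_sequence

MHC_CLASSES = ("I", "II")
EXON_LABELS = (2, 3, 4)

#: exon screened for premature stop codons, per class (the peptide-binding
#: exon: exon 3 of class I, exon 2 of class II)
SCREENING_EXON = {"I": 3, "II": 2}


@dataclass(frozen=True)
class ExonSeqRecord:
    """One MHC exon nucleotide sequence (coding strand) with its metadata."""

    seq_id: str
    species: str
    order_name: str
    mhc_class: str
    exon_label: int
    sequence: str

    def __post_init__(self) -> None:
        if self.mhc_class not in MHC_CLASSES:
            raise ValueError(f"mhc_class must be one of {MHC_CLASSES}")
        if self.exon_label not in EXON_LABELS:
            raise ValueError(f"exon_label must be one of {EXON_LABELS}")
        if len(self.sequence) < 100:
            raise ValueError("exon sequences shorter than 100 bp are excluded")
        validate_sequence(self.sequence, GENOME_ALPHABET, "exon sequence")


@dataclass
class GenomeAssembly:
    """A genome assembly: an ordered map of contig id to sequence."""

    assembly_id: str
    contigs: dict[str, str]
    technology_tag: str = "synthetic"

    def __post_init__(self) -> None:
        if self.technology_tag not in ("TGS", "NGS", "synthetic"):
            raise ValueError("technology_tag must be TGS, NGS or synthetic")
        for cid, seq in self.contigs.items():
            validate_sequence(seq, GENOME_ALPHABET, f"contig {cid}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def n50(self) -> int:
        """Contig N50: shortest length among contigs covering half the assembly."""
        lengths = sorted((len(s) for s in self.contigs.values()), reverse=True)
        if not lengths:
            raise ValueError("empty assembly has no N50")
        half = sum(lengths) / 2
        acc = 0
        for n in lengths:
            acc += n
            if acc >= half:
                return n
        return lengths[-1]


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment match of a query on a genome contig.

    ``start``/``end`` are plus-strand 0-based half-open contig coordinates;
    ``query_start``/``query_end`` refer to the query in its own orientation.
    ``frame_anchor`` is the offset into the (query-oriented) hit subsequence
    at which a codon begins, derived from the query alignment start.
    """

    query_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    identity: float
    query_start: int
    query_end: int
    score: float
    mhc_class: Optional[str] = None
    exon_label: Optional[int] = None
    frame_anchor: int = 0
    #: full query length when known; lets downstream consumers reconstruct
    #: the complete exon window around an end-trimmed local alignment
    query_length: Optional[int] = None
    #: gap-free alignment runs as (query_offset, subject_offset, length)
    #: triples, both in query orientation; subject offsets are relative to
    #: the start of the (oriented) hit subsequence.  None when the hit came
    #: from a tabular file that does not carry the alignment path.
    blocks: Optional[tuple[tuple[int, int, int], ...]] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError("invalid hit span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlap(self, other: "AlignmentHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class LocusCall:
    """A called MHC locus: exon 2, 3 and 4 hits of one class within 2 kb."""

    locus_id: str
    contig_id: str
    mhc_class: str
    strand: str
    exon_hits: dict[int, AlignmentHit]
    is_pseudogene: bool = False
    stop_codon_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.exon_hits) != set(EXON_LABELS):
            raise ValueError("a locus call requires hits for exons 2, 3 and 4")

    @property
    def span(self) -> tuple[int, int]:
        starts = [h.start for h in self.exon_hits.values()]
        ends = [h.end for h in self.exon_hits.values()]
        return (min(starts), max(ends))


@dataclass
class PartialCluster:
    """Exon hits that could not be promoted to a locus, with the reason."""

    contig_id: str
    mhc_class: str
    hits: list[AlignmentHit]
    reason: str  # missing_exon | gap_exceeded | strand_conflict

    def __post_init__(self) -> None:
        if self.reason not in ("missing_exon", "gap_exceeded", "strand_conflict"):
            raise ValueError(f"unknown reason {self.reason!r}")

    @property
    def present_exons(self) -> frozenset[int]:
        return frozenset(h.exon_label for h in self.hits if h.exon_label is not None)


@dataclass
class SpeciesLocusRecord:
    """One row of the 34-species locus-count table.

    ``predicted_*`` counts may be fractional when averaged over several
    assemblies of the same species (zebra finch); ``stop_*`` are the counts
    of loci whose peptide-binding exon carries a premature stop codon (the
    parenthesised numbers of the published table).
    """

    species: str
    order_name: str
    is_passerine: bool
    predicted_I: float
    predicted_II: float
    published_I: Optional[float] = None
    published_II: Optional[float] = None
    stop_I: float = 0.0
    stop_II: float = 0.0
    common_name: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        for name in ("predicted_I", "predicted_II", "stop_I", "stop_II"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.stop_I > self.predicted_I or self.stop_II > self.predicted_II:
            raise ValueError("stop-codon locus count cannot exceed total locus count")


@dataclass(frozen=True)
class ConsensusQuery:
    """Degenerate-base consensus used as a search probe."""

    query_id: str
    level: str  # species | order | global
    mhc_class: str
    exon_label: int
    sequence: str
    source_cluster: Optional["SequenceCluster"] = None

    def __post_init__(self) -> None:
        if self.level not in ("species", "order", "global"):
            raise ValueError("level must be species, order or global")
        if not 100 <= len(self.sequence) <= 1000:
            raise ValueError("consensus query length must be within [100, 1000]")
        validate_sequence(self.sequence, IUPAC_ALPHABET, "consensus query")
        if degeneracy_fraction(self.sequence) > 0.5:
            raise ValueError("consensus query degeneracy exceeds 0.5")


@dataclass(frozen=True)
class SequenceCluster:
    """A cluster of exon sequences at one level of the consensus hierarchy."""

    level: str
    member_ids: frozenset[str]
    representative_id: str
    mhc_class: str
    exon_label: int

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a cluster member")


@dataclass(frozen=True)
class DuplicationBlock:
    """A pair of duplicated spans on one contig, from the self-dotplot."""

    contig_id: str
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    length: int
    orientation: str  # direct | inverted

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError("orientation must be direct or inverted")
        if self.span_a > self.span_b:
            raise ValueError("span_a must precede span_b")
        if self.span_a == self.span_b:
            raise ValueError("duplication block spans must differ")


@dataclass
class DuplicationUnitClassification:
    contig_id: str
    pattern: str  # co_duplication | classI_only | classII_only | none
    participating_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pattern not in ("co_duplication", "classI_only", "classII_only", "none"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass
class TruthRecord:
    """Ground truth for one planted locus in a simulated genome."""

    locus_id: str
    contig_id: str
    mhc_class: str
    exon_spans: dict[int, tuple[int, int]]
    strand: str
    is_pseudogene: bool
    planted_stop_position: Optional[int] = None
    duplication_unit_id: Optional[str] = None
    is_split: bool = False  # locus straddles a fragmentation breakpoint

    def __post_init__(self) -> None:
        if not self.is_split and self.is_pseudogene != (self.planted_stop_position is not None):
            raise ValueError("pseudogene flag must match planted stop position")
        spans = sorted(self.exon_spans.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if e1 > s2:
                raise ValueError("planted exon spans must be disjoint")

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exon_spans.values()),
                max(e for _, e in self.exon_spans.values()))
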