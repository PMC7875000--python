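"""Hierarchical construction of degenerate consensus search queries.

Exon sequences are clustered sequentially at three levels -- within species
(>=85% identity), within taxonomic order (>=80%), and across all orders
(>=50%) -- and each terminal cluster is collapsed into one IUPAC consensus
sequence.  The degenerate positions deliberately keep common polymorphism
in the query so a single probe matches diverged paralogs.

Clustering is greedy centroid (UCLUST-like): sequences are visited longest
first; the first sequence founds a cluster and becomes its representative;
every later sequence joins the first representative it matches at or above
the threshold, otherwise it founds a new cluster.  This is deterministic
given the input and the seed used for representative sampling.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alphabet import code_for, validate_sequence, GENOME_ALPHABET
from .io_formats import read_fasta, write_fasta
from .model import ConsensusQuery, ExonSeqRecord, SequenceCluster
from .pairwise import align_global, alignment_identity


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds of the three clustering levels and the consensus rule.

    ``consensus_inclusion_fraction`` is the minimum within-column base
    frequency for a base to be folded into the degenerate consensus code.
    """

    species_threshold: float = 0.85
    order_threshold: float = 0.80
    global_threshold: float = 0.50
    consensus_inclusion_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.global_threshold <= self.order_threshold
                <= self.species_threshold <= 1):
            raise ValueError("thresholds must satisfy 0 < global <= order <= species <= 1")
        if not 0 < self.consensus_inclusion_fraction <= 1:
            raise ValueError("consensus_inclusion_fraction must be in (0, 1]")


def pairwise_identity(a: str, b: str, degenerate: bool = True) -> float:
    """Identity of the best global alignment, terminal gaps excluded.

    Symmetric, in [0, 1].  With ``degenerate`` (default) compatible IUPAC
    codes count as matches, so a sequence can be scored against a
    degenerate consensus.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    return alignment_identity(align_global(a, b), degenerate=degenerate)


def cluster_by_identity(records: Sequence[ExonSeqRecord], threshold: float,
                        level: str = "species") -> list[SequenceCluster]:
    """Greedy centroid clustering of exon records at an identity threshold."""
    if not records:
        return []
    classes = {r.mhc_class for r in records}
    exons = {r.exon_label for r in records}
    if len(classes) > 1 or len(exons) > 1:
        raise ValueError("all records must share mhc_class and exon_label")
    mhc_class, exon_label = classes.pop(), exons.pop()

    # longest first; ties broken by input order (stable sort)
    order = sorted(range(len(records)), key=lambda i: -len(records[i].sequence))
    reps: list[int] = []
    members: dict[int, list[int]] = {}
    for i in order:
        placed = False
        for rep in reps:
            if pairwise_identity(records[i].sequence, records[rep].sequence) >= threshold:
                members[rep].append(i)
                placed = True
                break
        if not placed:
            reps.append(i)
            members[i] = [i]
    return [
        SequenceCluster(
            level=level,
            member_ids=frozenset(records[i].seq_id for i in members[rep]),
            representative_id=records[rep].seq_id,
            mhc_class=mhc_class,
            exon_label=exon_label,
        )
        for rep in reps
    ]


# ---------------------------------------------------------------------------
# Multiple alignment + consensus
# ---------------------------------------------------------------------------

def _mafft_align_raw(seqs: Sequence[str]) -> list[str]:
    """Multiple alignment via mafft, keeping gap characters."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH; required for multi-member consensus")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        write_fasta([(f"s{i}", s) for i, s in enumerate(seqs)], fin)
        out = subprocess.run(
            ["mafft", "--auto", "--quiet", str(fin)],
            capture_output=True, text=True, check=True,
        )
    rows: dict[str, list[str]] = {}
    name = None
    for line in out.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            rows[name] = []
        elif name is not None:
            rows[name].append(line.strip().upper())
    return ["".join(rows[f"s{i}"]) for i in range(len(seqs))]


def build_consensus(members: Sequence[str], inclusion_fraction: float = 0.25,
                    align: bool = True) -> str:
    """IUPAC consensus of a cluster.

    Per aligned column, every base whose frequency among non-gap residues is
    at least ``inclusion_fraction`` is folded into the emitted code (the
    majority base is always included); columns gapped in at least half the
    members are dropped.  With ``align`` (default) members are multiply
    aligned first; pass ``align=False`` for pre-aligned, equal-length input.
    """
    if not members:
        raise ValueError("build_consensus requires at least one member")
    if len(members) == 1:
        return members[0]
    if align:
        aligned = _mafft_align_raw(members)
    else:
        if len({len(m) for m in members}) != 1:
            raise ValueError("pre-aligned members must have equal length")
        aligned = list(members)
    n = len(aligned)
    width = len(aligned[0])
    out: list[str] = []
    for col in range(width):
        chars = [row[col] for row in aligned]
        gaps = sum(1 for c in chars if c == "-")
        if gaps * 2 >= n:
            continue
        counts: dict[str, int] = defaultdict(int)
        for c in chars:
            if c in "ACGT":
                counts[c] += 1
        if not counts:
            out.append("N")
            continue
        total = sum(counts.values())
        best = max(counts.values())
        included = {b for b, k in counts.items()
                    if k / total >= inclusion_fraction or k == best}
        out.append(code_for(included))
    return "".join(out)


# ---------------------------------------------------------------------------
# The three-level hierarchy
# ---------------------------------------------------------------------------

def hierarchical_consensus(records: Sequence[ExonSeqRecord],
                           config: ConsensusConfig = ConsensusConfig(),
                           seed: int = 1) -> list[ConsensusQuery]:
    """Sequential species -> order -> global clustering and consensus.

    Stage 1 clusters within each species at ``species_threshold`` and samples
    one random representative per cluster (seeded).  Stage 2 clusters those
    representatives within each order at ``order_threshold``; the cluster
    centroid carries forward.  Stage 3 clusters the order-level
    representatives across all orders at ``global_threshold`` and each
    terminal cluster is collapsed into one degenerate consensus query.
    Queries are produced per (mhc_class, exon_label) group.
    """
    if not records:
        return []
    rng = np.random.default_rng(seed)
    by_record = {r.seq_id: r for r in records}
    queries: list[ConsensusQuery] = []

    groups: dict[tuple[str, int], list[ExonSeqRecord]] = defaultdict(list)
    for r in records:
        groups[(r.mhc_class, r.exon_label)].append(r)

    for (mhc_class, exon_label) in sorted(groups):
        grp = groups[(mhc_class, exon_label)]

        # stage 1: within species
        species_reps: list[ExonSeqRecord] = []
        by_species: dict[str, list[ExonSeqRecord]] = defaultdict(list)
        for r in grp:
            by_species[r.species].append(r)
        for species in sorted(by_species):
            clusters = cluster_by_identity(by_species[species],
                                           config.species_threshold, level="species")
            for cl in clusters:
                chosen = rng.choice(sorted(cl.member_ids))
                species_reps.append(by_record[str(chosen)])

        # stage 2: within order; remember which species representatives stand
        # behind each order-level representative
        order_reps: list[ExonSeqRecord] = []
        behind: dict[str, frozenset[str]] = {}
        by_order: dict[str, list[ExonSeqRecord]] = defaultdict(list)
        for r in species_reps:
            by_order[r.order_name].append(r)
        for order_name in sorted(by_order):
            clusters = cluster_by_identity(by_order[order_name],
                                           config.order_threshold, level="order")
            for cl in clusters:
                order_reps.append(by_record[cl.representative_id])
                behind[cl.representative_id] = cl.member_ids

        # stage 3: across all orders; consensus built from the species
        # representatives behind each member of the terminal cluster
        terminal = cluster_by_identity(order_reps, config.global_threshold,
                                       level="global")
        for i, cl in enumerate(terminal):
            member_ids = sorted(set().union(*(behind[rid] for rid in cl.member_ids)))
            member_seqs = [by_record[sid].sequence for sid in member_ids]
            consensus = build_consensus(member_seqs,
                                        config.consensus_inclusion_fraction)
            queries.append(ConsensusQuery(
                query_id=f"{mhc_class}_e{exon_label}_q{i:02d}",
                level="global",
                mhc_class=mhc_class,
                exon_label=exon_label,
                sequence=consensus,
                source_cluster=cl,
            ))
    return queries


def records_from_fasta(fasta_path, meta: dict[str, dict]) -> list[ExonSeqRecord]:
    """Combine a FASTA file and a metadata mapping into exon records."""
    records = []
    for seq_id, seq in read_fasta(fasta_path):
        if seq_id not in meta:
            raise ValueError(f"no metadata for sequence {seq_id!r}")
        m = meta[seq_id]
        validate_sequence(seq, GENOME_ALPHABET, f"exon {seq_id}")
        records.append(ExonSeqRecord(
            seq_id=seq_id, species=m["species"], order_name=m["order_name"],
            mhc_class=m["mhc_class"], exon_label=int(m["exon_label"]), sequence=seq,
        ))
    return records
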