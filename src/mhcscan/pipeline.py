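"""End-to-end orchestration: consensus -> search -> loci -> structure -> stats.

Every stage writes plain standard formats (FASTA, 12-column hit table,
GFF3, TSV) so any stage can be re-run standalone, and a JSON manifest
records config, input checksums and per-stage record counts; identical
inputs and seed reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .consensus_builder import ConsensusConfig, hierarchical_consensus, records_from_fasta
from .homology_search import SearchConfig, dedupe_hits, run_external_backend, search_all
from .io_formats import (parse_query_id, read_exon_metadata, read_fasta,
                         write_fasta, write_hits_table, write_locus_gff)
from .locus_caller import (LocusCallerConfig, call_loci, count_loci,
                           screen_pseudogenes)
from .model import ConsensusQuery, GenomeAssembly
from .structure_analyzer import (DotplotConfig, classify_duplication,
                                 find_duplicated_blocks, multilocus_contigs,
                                 self_dotplot, write_arrangement_tsv)


class PipelineError(RuntimeError):
    """A stage failed; message names the stage."""


@dataclass
class RunConfig:
    genome_fasta: str
    out_dir: str
    queries_fasta: Optional[str] = None     # either pre-built queries ...
    exons_fasta: Optional[str] = None       # ... or exons + metadata to build them
    exons_meta: Optional[str] = None
    backend_cmd: Optional[str] = None
    seed: int = 1
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    caller: LocusCallerConfig = field(default_factory=LocusCallerConfig)
    dotplot: DotplotConfig = field(default_factory=DotplotConfig)

    def validate(self) -> None:
        if not Path(self.genome_fasta).exists():
            raise PipelineError(f"validation: genome FASTA not found: {self.genome_fasta}")
        if self.queries_fasta is None and (self.exons_fasta is None
                                           or self.exons_meta is None):
            raise PipelineError("validation: need either queries_fasta or "
                                "exons_fasta + exons_meta")
        for p in (self.queries_fasta, self.exons_fasta, self.exons_meta):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"validation: input not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_genome(path: str | Path, technology_tag: str = "synthetic") -> GenomeAssembly:
    contigs = dict(read_fasta(path))
    return GenomeAssembly(assembly_id=Path(path).stem, contigs=contigs,
                          technology_tag=technology_tag)


def queries_from_fasta(path: str | Path) -> list[ConsensusQuery]:
    queries = []
    for qid, seq in read_fasta(path):
        mhc_class, exon = parse_query_id(qid)
        if mhc_class is None:
            raise PipelineError(f"query id {qid!r} does not encode class/exon "
                                "(expected e.g. 'II_e2_q00')")
        queries.append(ConsensusQuery(query_id=qid, level="global",
                                      mhc_class=mhc_class, exon_label=exon,
                                      sequence=seq))
    return queries


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "mhcscan", "version": __version__, "seed": config.seed,
        "inputs": {}, "stages": {}, "outputs": {},
    }
    genome_path = Path(config.genome_fasta)
    manifest["inputs"][str(genome_path)] = _sha256(genome_path)

    # stage 1: queries
    try:
        if config.queries_fasta is not None:
            queries = queries_from_fasta(config.queries_fasta)
            manifest["inputs"][config.queries_fasta] = _sha256(Path(config.queries_fasta))
        else:
            meta = read_exon_metadata(config.exons_meta)
            records = records_from_fasta(config.exons_fasta, meta)
            queries = hierarchical_consensus(records, config.consensus,
                                             seed=config.seed)
            qpath = out / "queries.fasta"
            write_fasta([(q.query_id, q.sequence) for q in queries], qpath)
            manifest["outputs"]["queries.fasta"] = _sha256(qpath)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"consensus stage failed: {exc}") from exc
    manifest["stages"]["consensus"] = {"n_queries": len(queries)}

    try:
        genome = load_genome(genome_path)
    except Exception as exc:
        raise PipelineError(f"validation: unreadable genome FASTA: {exc}") from exc
    if not genome.contigs:
        raise PipelineError("validation: genome has no contigs")

    # stage 2: search
    try:
        if config.backend_cmd:
            qpath = out / "queries.fasta"
            if config.queries_fasta is not None:
                qpath = Path(config.queries_fasta)
            hits = run_external_backend(qpath, genome_path, config.backend_cmd)
        else:
            hits = search_all(queries, genome, config.search)
        hits_path = out / "hits.tsv"
        write_hits_table(hits, hits_path)
        manifest["outputs"]["hits.tsv"] = _sha256(hits_path)
    except Exception as exc:
        raise PipelineError(f"search stage failed: {exc}") from exc
    manifest["stages"]["search"] = {"n_hits": len(hits)}

    # stage 3: locus calling + pseudogene screen
    try:
        deduped = dedupe_hits(hits)
        loci, partials = call_loci(deduped, config.caller, genome=genome)
        screen_pseudogenes(loci, genome)
        summary = count_loci(loci, partials)
        gff_path = out / "loci.gff3"
        write_locus_gff(loci, gff_path,
                        contig_lengths={c: len(s) for c, s in genome.contigs.items()})
        manifest["outputs"]["loci.gff3"] = _sha256(gff_path)
        spath = out / "summary.tsv"
        with open(spath, "w") as fh:
            fh.write("assembly_id\tclass\tn_loci\tn_pseudogene\tn_partial_clusters\n")
            for cls in ("I", "II"):
                fh.write(f"{genome.assembly_id}\t{cls}\t{summary.n_loci[cls]}\t"
                         f"{summary.n_pseudogene[cls]}\t"
                         f"{summary.n_partial_clusters[cls]}\n")
        manifest["outputs"]["summary.tsv"] = _sha256(spath)
    except Exception as exc:
        raise PipelineError(f"locus-calling stage failed: {exc}") from exc
    manifest["stages"]["call_loci"] = {
        "n_loci": len(loci), "n_partials": len(partials),
        "class_I": summary.n_loci["I"], "class_II": summary.n_loci["II"],
        "pseudo_I": summary.n_pseudogene["I"], "pseudo_II": summary.n_pseudogene["II"],
    }

    # stage 4: structure
    try:
        multi = multilocus_contigs(loci)
        blocks = []
        for contig_id, _group in multi:
            seq = genome.contigs[contig_id]
            if len(seq) >= 2 * config.dotplot.word_size:
                matches = self_dotplot(seq, config.dotplot)
                blocks.extend(find_duplicated_blocks(matches, config.dotplot,
                                                     contig_id=contig_id))
        classifications = classify_duplication(blocks, loci)
        bpath = out / "blocks.tsv"
        with open(bpath, "w") as fh:
            fh.write("contig_id\tspan_a_start\tspan_a_end\tspan_b_start\t"
                     "span_b_end\tlength\torientation\tpattern\n")
            for block, cl in zip(blocks, classifications):
                fh.write(f"{block.contig_id}\t{block.span_a[0]}\t{block.span_a[1]}\t"
                         f"{block.span_b[0]}\t{block.span_b[1]}\t{block.length}\t"
                         f"{block.orientation}\t{cl.pattern}\n")
        manifest["outputs"]["blocks.tsv"] = _sha256(bpath)
        apath = out / "arrangement.tsv"
        write_arrangement_tsv(loci, apath)
        manifest["outputs"]["arrangement.tsv"] = _sha256(apath)
    except Exception as exc:
        raise PipelineError(f"structure stage failed: {exc}") from exc
    manifest["stages"]["structure"] = {
        "n_multilocus_contigs": len(multi), "n_duplication_blocks": len(blocks),
    }

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
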