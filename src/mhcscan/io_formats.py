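"""Readers and writers for the on-disk artifacts of the pipeline.

FASTA (80-column wrapped on write), the 12-column tab-separated hit table
(the ubiquitous tabular local-search dialect, 1-based inclusive coordinates,
minus strand encoded by a descending subject interval), GFF3 for locus
calls, and the packaged 34-species locus-count table.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .alphabet import IUPAC_ALPHABET, validate_sequence
from .model import AlignmentHit, LocusCall, SpeciesLocusRecord


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


_QUERY_ID_RE = re.compile(r"(?:^|_)(II|I)_e([234])(?:_|$)")


def parse_query_id(query_id: str) -> tuple[Optional[str], Optional[int]]:
    """Extract (mhc_class, exon_label) from a query id such as ``II_e2_q01``.

    Returns (None, None) when the id does not follow the convention.
    """
    m = _QUERY_ID_RE.search(query_id)
    if not m:
        return None, None
    return m.group(1), int(m.group(2))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA file.

    Sequences are uppercased, U is mapped to T, and any character outside
    the IUPAC nucleotide alphabet (plus N) is rejected with a ParseError
    naming the line.  Record order is preserved.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    header: Optional[str] = None
    chunks: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{lineno}: record {header!r} has an empty sequence")
        records.append((header, seq))
        header, chunks = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence before first header")
                seq = line.upper().replace("U", "T")
                bad = set(seq) - IUPAC_ALPHABET
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal sequence characters {sorted(bad)}"
                    )
                chunks.append(seq)
        flush(lineno + 1)
    if not records:
        raise ParseError(f"{path}:1: empty FASTA file")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            validate_sequence(seq.upper(), IUPAC_ALPHABET, f"record {name}")
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# 12-column hit table
# ---------------------------------------------------------------------------

def read_hits_table(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tabular hit file into internal coordinates.

    External: 1-based inclusive; subject start > end encodes the minus
    strand.  Internal: 0-based half-open on the plus strand with a strand
    flag.  Lines starting with ``#`` are skipped.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            (query_id, subject_id, pct_ident, aln_len, _mm, _go,
             q_start, q_end, s_start, s_end, _evalue, bitscore) = cols
            try:
                qs, qe = int(q_start), int(q_end)
                ss, se = int(s_start), int(s_end)
                ident = float(pct_ident) / 100.0
                score = float(bitscore)
                int(aln_len)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if ss <= se:
                start, end, strand = ss - 1, se, "+"
            else:
                start, end, strand = se - 1, ss, "-"
            mhc_class, exon_label = parse_query_id(query_id)
            q0 = qs - 1
            hits.append(AlignmentHit(
                query_id=query_id, contig_id=subject_id,
                start=start, end=end, strand=strand,
                identity=ident, query_start=q0, query_end=qe,
                score=score, mhc_class=mhc_class, exon_label=exon_label,
                frame_anchor=(-q0) % 3,
            ))
    return hits


def write_hits_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect (inverse of read_hits_table)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                ss, se = h.start + 1, h.end
            else:
                ss, se = h.end, h.start + 1
            aln_len = max(h.end - h.start, h.query_end - h.query_start)
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.contig_id, f"{h.identity * 100:.2f}", aln_len,
                0, 0, h.query_start + 1, h.query_end, ss, se,
                "0.0", f"{h.score:.1f}",
            )) + "\n")


# ---------------------------------------------------------------------------
# GFF3 locus calls
# ---------------------------------------------------------------------------

def write_locus_gff(loci: Iterable[LocusCall], path: str | Path,
                    contig_lengths: Optional[dict[str, int]] = None) -> None:
    """Write locus calls as GFF3: one gene row per locus, one exon row per hit."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            start, end = locus.span
            if contig_lengths is not None:
                clen = contig_lengths.get(locus.contig_id)
                if clen is None:
                    raise ValueError(f"locus on unknown contig {locus.contig_id}")
                if end > clen:
                    raise ValueError(f"locus {locus.locus_id} extends past contig end")
            attrs = [
                f"ID={locus.locus_id}",
                f"mhc_class={locus.mhc_class}",
                f"pseudogene={'true' if locus.is_pseudogene else 'false'}",
            ]
            if locus.stop_codon_positions:
                attrs.append("stop_codon_positions="
                             + ",".join(str(p) for p in locus.stop_codon_positions))
            fh.write("\t".join((
                locus.contig_id, "mhcscan", "gene", str(start + 1), str(end),
                ".", locus.strand, ".", ";".join(attrs),
            )) + "\n")
            for exon in sorted(locus.exon_hits):
                h = locus.exon_hits[exon]
                ex_attrs = (
                    f"ID={locus.locus_id}.e{exon};Parent={locus.locus_id};"
                    f"exon_label={exon};identity={h.identity:.4f};query_id={h.query_id}"
                )
                fh.write("\t".join((
                    locus.contig_id, "mhcscan", "exon", str(h.start + 1), str(h.end),
                    f"{h.score:.1f}", h.strand, ".", ex_attrs,
                )) + "\n")


def read_locus_gff(path: str | Path) -> list[LocusCall]:
    """Reconstruct locus calls written by write_locus_gff."""
    genes: dict[str, dict] = {}
    exons: dict[str, dict[int, AlignmentHit]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns")
            contig, _src, ftype, start, end, score, strand, _frame, attr_s = cols
            attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv)
            if ftype == "gene":
                genes[attrs["ID"]] = {
                    "contig_id": contig, "strand": strand,
                    "mhc_class": attrs.get("mhc_class"),
                    "pseudogene": attrs.get("pseudogene") == "true",
                    "stops": [int(p) for p in attrs.get("stop_codon_positions", "").split(",")
                              if p],
                }
            elif ftype == "exon":
                parent = attrs["Parent"]
                exon = int(attrs["exon_label"])
                q0 = int(start) - 1
                hit = AlignmentHit(
                    query_id=attrs.get("query_id", ""), contig_id=contig,
                    start=q0, end=int(end), strand=strand,
                    identity=float(attrs.get("identity", "1.0")),
                    query_start=0, query_end=int(end) - q0,
                    score=float(score) if score != "." else 0.0,
                    mhc_class=genes.get(parent, {}).get("mhc_class"),
                    exon_label=exon,
                )
                exons.setdefault(parent, {})[exon] = hit
    loci = []
    for locus_id, g in genes.items():
        loci.append(LocusCall(
            locus_id=locus_id, contig_id=g["contig_id"], mhc_class=g["mhc_class"],
            strand=g["strand"], exon_hits=exons.get(locus_id, {}),
            is_pseudogene=g["pseudogene"], stop_codon_positions=g["stops"],
        ))
    return loci


# ---------------------------------------------------------------------------
# Exon metadata and the packaged species table
# ---------------------------------------------------------------------------

def read_exon_metadata(path: str | Path) -> dict[str, dict]:
    """Read the TSV mapping seq_id -> species/order/class/exon."""
    meta: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"seq_id", "species", "order_name", "mhc_class", "exon_label"}
        missing = required - set(header)
        if missing:
            raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
        idx = {name: header.index(name) for name in header}
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            meta[cols[idx["seq_id"]]] = {
                "species": cols[idx["species"]],
                "order_name": cols[idx["order_name"]],
                "mhc_class": cols[idx["mhc_class"]],
                "exon_label": int(cols[idx["exon_label"]]),
            }
    return meta


def _opt_float(s: str) -> Optional[float]:
    return None if s in ("", "NA", "na", ".") else float(s)


def load_table1_fixture() -> list[SpeciesLocusRecord]:
    """Load the packaged 34-species table of published vs predicted locus counts.

    Fractional predicted counts appear where the published study averaged
    several assemblies of the same species (zebra finch).
    """
    text = resources.files("mhcscan").joinpath("data/species_locus_counts.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    idx = {name: header.index(name) for name in header}
    records = []
    for ln in lines[1:]:
        cols = ln.split("\t")
        records.append(SpeciesLocusRecord(
            species=cols[idx["species"]],
            common_name=cols[idx["common_name"]],
            order_name=cols[idx["order_name"]],
            is_passerine=cols[idx["is_passerine"]] == "1",
            published_I=_opt_float(cols[idx["published_I"]]),
            predicted_I=float(cols[idx["predicted_I"]]),
            published_II=_opt_float(cols[idx["published_II"]]),
            predicted_II=float(cols[idx["predicted_II"]]),
            stop_I=float(cols[idx["stop_I"]]),
            stop_II=float(cols[idx["stop_II"]]),
            notes=cols[idx["notes"]] if "notes" in idx and len(cols) > idx["notes"] else "",
        ))
    return records
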