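"""Seed-and-extend homology search of consensus queries against contigs.

Seeding uses exact word matches of ``word_size`` bases; degenerate query
positions are expanded (capped) so a degenerate word still seeds.  Seeds
are grouped into candidate windows and each window is resolved by an exact
affine-gap Smith-Waterman alignment of the query against the window, which
replaces heuristic x-drop extension: the window padding bounds how far an
alignment can extend past its seeds, and the DP then finds the maximal
scoring local alignment exactly.  Both strands are scanned by searching the
reverse-complemented query against the plus strand.

An external tabular search tool (e.g. blastn with 12-column output) can be
slotted in through :func:`run_external_backend`; downstream stages are
agnostic to the hit provenance.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .alphabet import expand_word, revcomp
from .io_formats import read_hits_table
from .model import AlignmentHit, ConsensusQuery, GenomeAssembly
from .pairwise import alignment_identity, make_aligner


@dataclass(frozen=True)
class SearchConfig:
    """Seeding and acceptance thresholds for the built-in search.

    Defaults accept matches down to 75% identity, comfortably below the
    83-95% similarity range observed between consensus probes and their
    true genomic targets, while rejecting chance alignments.
    """

    word_size: int = 11
    min_identity: float = 0.75
    min_query_coverage: float = 0.50
    x_drop: float = 20.0  # retained knob; sizes the window padding
    seed_expansion_cap: int = 64

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_query_coverage <= 1:
            raise ValueError("min_query_coverage must be in (0, 1]")


class BackendError(RuntimeError):
    """External search backend failed; message carries its diagnostics."""


# ---------------------------------------------------------------------------
# contig word index
# ---------------------------------------------------------------------------

#: seeding skips words occurring more often than this (repeat guard)
MAX_WORD_POSITIONS = 10000


def _index_contig(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _query_words(qseq: str, k: int, cap: int) -> dict[str, list[int]]:
    """Map each expanded plain-base word to the query positions it seeds."""
    words: dict[str, list[int]] = defaultdict(list)
    for qpos in range(len(qseq) - k + 1):
        expansions = expand_word(qseq[qpos : qpos + k], cap=cap)
        if expansions is None:
            continue  # too degenerate; neighbouring seeds recover the hit
        for w in expansions:
            words[w].append(qpos)
    return dict(words)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _align_window(qseq: str, window: str, win_off: int, config: SearchConfig,
                  results: list[tuple[int, int, int, int, float, float]],
                  depth: int = 0) -> None:
    """Best local alignment of query vs window; recurse into the flanks so
    multiple copies inside one window are all found."""
    if depth > 6 or len(window) < config.word_size:
        return
    aligner = make_aligner("local")
    alignments = aligner.align(window, qseq)
    try:
        aln = alignments[0]
    except IndexError:
        return
    if aln.score <= 0:
        return
    blocks_t, blocks_q = aln.aligned
    if len(blocks_t) == 0:
        return
    t_start, t_end = int(blocks_t[0][0]), int(blocks_t[-1][1])
    q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
    identity = alignment_identity(aln, degenerate=True)
    coverage = (q_end - q_start) / len(qseq)
    if identity >= config.min_identity and coverage >= config.min_query_coverage:
        runs = tuple((int(qs), int(ts) + win_off, int(te) - int(ts))
                     for (ts, te), (qs, _qe) in zip(blocks_t, blocks_q))
        results.append((win_off + t_start, win_off + t_end,
                        q_start, q_end, identity, float(aln.score), runs))
    # flanks may hold further (tandem) copies
    min_len = max(config.word_size, int(config.min_query_coverage * len(qseq)))
    if t_start >= min_len:
        _align_window(qseq, window[:t_start], win_off, config, results, depth + 1)
    if len(window) - t_end >= min_len:
        _align_window(qseq, window[t_end:], win_off + t_end, config, results, depth + 1)


def _search_contig(query: ConsensusQuery, contig_id: str, contig_index: dict[str, list[int]],
                   contig_seq: str, config: SearchConfig) -> list[AlignmentHit]:
    qlen = len(query.sequence)
    pad = int(max(50, config.x_drop, qlen // 4))
    hits: list[AlignmentHit] = []
    oriented = (("+", query.sequence), ("-", revcomp(query.sequence)))
    for strand, qseq in oriented:
        qwords = _query_words(qseq, config.word_size, config.seed_expansion_cap)
        windows: list[tuple[int, int]] = []
        for word, qposs in qwords.items():
            positions = contig_index.get(word, ())
            if len(positions) > MAX_WORD_POSITIONS:
                continue
            for spos in positions:
                for qpos in qposs:
                    anchor = spos - qpos
                    windows.append((max(0, anchor - pad),
                                    min(len(contig_seq), anchor + qlen + pad)))
        raw: list[tuple] = []
        for w_start, w_end in _merge_intervals(windows):
            _align_window(qseq, contig_seq[w_start:w_end], w_start, config, raw)
        for s_start, s_end, q_start, q_end, identity, score, runs in raw:
            if strand == "+":
                blocks = tuple((q_off, s_abs - s_start, length)
                               for q_off, s_abs, length in runs)
            else:
                # rc-query coordinates -> original query orientation, and
                # plus-strand subject runs -> offsets in the revcomp'd span
                q_start, q_end = qlen - q_end, qlen - q_start
                blocks = tuple(sorted(
                    (qlen - (q_off + length), s_end - (s_abs + length), length)
                    for q_off, s_abs, length in runs))
            hits.append(AlignmentHit(
                query_id=query.query_id, contig_id=contig_id,
                start=s_start, end=s_end, strand=strand,
                identity=identity, query_start=q_start, query_end=q_end,
                score=score, mhc_class=query.mhc_class, exon_label=query.exon_label,
                frame_anchor=(-q_start) % 3, query_length=qlen, blocks=blocks,
            ))
    return _merge_same_query(hits)


def _merge_same_query(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Collapse overlapping hits of one query, keeping the higher score."""
    hits = sorted(hits, key=lambda h: (h.start, -h.score))
    kept: list[AlignmentHit] = []
    for h in hits:
        merged = False
        for i, k in enumerate(kept):
            if h.overlap(k) > 0:
                if h.score > k.score:
                    kept[i] = h
                merged = True
                break
        if not merged:
            kept.append(h)
    return sorted(kept, key=lambda h: h.start)


def search(query: ConsensusQuery, genome: GenomeAssembly,
           config: SearchConfig = SearchConfig()) -> list[AlignmentHit]:
    """All qualifying local matches of one query across a genome."""
    return search_all([query], genome, config)


def search_all(queries: Sequence[ConsensusQuery], genome: GenomeAssembly,
               config: SearchConfig = SearchConfig()) -> list[AlignmentHit]:
    """Search several queries, sharing one word index per contig."""
    for q in queries:
        if config.word_size > len(q.sequence):
            raise ValueError(f"word_size exceeds query length for {q.query_id}")
    hits: list[AlignmentHit] = []
    for contig_id in genome.contigs:
        seq = genome.contigs[contig_id]
        if len(seq) < config.word_size:
            continue
        index = _index_contig(seq, config.word_size)
        for q in queries:
            hits.extend(_search_contig(q, contig_id, index, seq, config))
    return sorted(hits, key=lambda h: (h.contig_id, h.start, h.query_id, h.strand))


# ---------------------------------------------------------------------------
# de-duplication across queries
# ---------------------------------------------------------------------------

def dedupe_hits(hits: Sequence[AlignmentHit],
                overlap_fraction: float = 0.5) -> list[AlignmentHit]:
    """Collapse hits of the same class and exon that cover the same site.

    Hits whose spans reciprocally overlap by at least ``overlap_fraction``
    are connected; each connected component keeps its highest-identity hit.
    Hits of distinct exon labels are never collapsed.
    """
    groups: dict[tuple, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        groups[(h.contig_id, h.mhc_class, h.exon_label)].append(h)
    kept: list[AlignmentHit] = []
    for key in groups:
        grp = sorted(groups[key], key=lambda h: h.start)
        # union-find over reciprocal-overlap edges
        parent = list(range(len(grp)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                if grp[j].start >= grp[i].end:
                    break
                ov = grp[i].overlap(grp[j])
                li = grp[i].end - grp[i].start
                lj = grp[j].end - grp[j].start
                if ov >= overlap_fraction * li and ov >= overlap_fraction * lj:
                    parent[find(i)] = find(j)
        comps: dict[int, list[AlignmentHit]] = defaultdict(list)
        for i, h in enumerate(grp):
            comps[find(i)].append(h)
        for comp in comps.values():
            kept.append(max(comp, key=lambda h: (h.identity, h.score, -h.start)))
    return sorted(kept, key=lambda h: (h.contig_id, h.start, h.query_id))


# ---------------------------------------------------------------------------
# external backend
# ---------------------------------------------------------------------------

def run_external_backend(queries_path: str | Path, genome_path: str | Path,
                         backend_cmd: str) -> list[AlignmentHit]:
    """Run an external tabular search tool and parse its 12-column output.

    ``backend_cmd`` is a shell-style template with ``{queries}`` and
    ``{genome}`` placeholders (and optionally ``{out}``; without it the
    table is read from stdout), e.g.::

        blastn -query {queries} -subject {genome} -outfmt 6 -out {out}
    """
    with tempfile.TemporaryDirectory() as tmp:
        out_path = Path(tmp) / "hits.tsv"
        cmd = backend_cmd.format(queries=str(queries_path), genome=str(genome_path),
                                 out=str(out_path))
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
        if proc.returncode != 0:
            raise BackendError(
                f"backend exited with {proc.returncode}: {proc.stderr.strip()}")
        if "{out}" not in backend_cmd:
            out_path.write_text(proc.stdout)
        try:
            return read_hits_table(out_path)
        except Exception as exc:
            raise BackendError(f"unparseable backend output: {exc}") from exc
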