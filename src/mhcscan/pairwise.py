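"""Pairwise alignment helpers built on Bio.Align.PairwiseAligner.

One scoring scheme is used throughout the package: match 2, mismatch -3,
gap open -5, gap extend -2.  Degenerate (IUPAC) positions score as a match
whenever the two codes share a base, so consensus queries align against
plain genomic sequence without penalty at their degenerate columns.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .alphabet import IUPAC_ALPHABET, compatible

MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = -5.0
GAP_EXTEND = -2.0

# Stiffer gaps for *global identity* alignments.  With extension (-2)
# cheaper than a mismatch (-3), a score-optimal global alignment of two
# divergent sequences degenerates into gap shuffling and its identity
# saturates near 0.5 even for unrelated DNA, defeating any 50% clustering
# threshold.  Making a gap column dearer than a mismatch keeps divergent
# alignments substitution-dominated, so identity tracks true similarity.
IDENT_GAP_OPEN = -10.0
IDENT_GAP_EXTEND = -6.0

_ALPHABET = "".join(sorted(IUPAC_ALPHABET))


@lru_cache(maxsize=None)
def iupac_matrix(match: float = MATCH, mismatch: float = MISMATCH):
    """Substitution matrix over IUPAC codes: compatible codes score as match."""
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = match if compatible(a, b) else mismatch
    return m


@lru_cache(maxsize=8)
def make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local" if mode == "local" else "global"
    aligner.substitution_matrix = iupac_matrix()
    if mode == "global":
        aligner.open_gap_score = IDENT_GAP_OPEN
        aligner.extend_gap_score = IDENT_GAP_EXTEND
    else:
        aligner.open_gap_score = GAP_OPEN
        aligner.extend_gap_score = GAP_EXTEND
    return aligner


def align_global(a: str, b: str):
    """Best global (Needleman-Wunsch, affine gaps) alignment of two sequences.

    Uses the stiff-gap identity scoring; end gaps are penalised in the
    score -- a cheap end-shifted overlap must not masquerade as high
    identity -- but terminal gap columns are still excluded from the
    identity denominator.
    """
    return next(iter(make_aligner("global").align(a, b)))


def align_local(a: str, b: str):
    """Best Smith-Waterman local alignment of two sequences."""
    return next(iter(make_aligner("local").align(a, b)))


def alignment_identity(alignment, degenerate: bool = True) -> float:
    """Matches / aligned columns, terminal gaps excluded.

    Internal gaps count as columns (and as non-matches).  With
    ``degenerate`` (default) compatible IUPAC codes count as matches.
    """
    a, b = alignment.target, alignment.query
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return 0.0
    matches = 0
    columns = 0
    prev_a_end = prev_b_end = None
    for (a_s, a_e), (b_s, b_e) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            # internal gap columns between aligned blocks
            columns += (a_s - prev_a_end) + (b_s - prev_b_end)
        for i, j in zip(range(a_s, a_e), range(b_s, b_e)):
            columns += 1
            ca, cb = a[i], b[j]
            if degenerate:
                if compatible(ca, cb):
                    matches += 1
            elif ca == cb:
                matches += 1
        prev_a_end, prev_b_end = a_e, b_e
    return matches / columns if columns else 0.0
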