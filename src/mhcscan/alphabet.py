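"""IUPAC nucleotide alphabet utilities.

Degenerate codes are the workhorse of this package: consensus queries carry
them, and the search treats a degenerate query position as matching any base
its code covers.  Genome contigs, by contrast, are restricted to A/C/G/T/N.
"""

from __future__ import annotations

from typing import Iterable

# code -> set of plain bases it covers
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

GENOME_ALPHABET = frozenset("ACGTN")
IUPAC_ALPHABET = frozenset(IUPAC_SETS)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMP_TABLE = str.maketrans(COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement, degenerate codes included."""
    return seq.translate(_COMP_TABLE)[::-1]


def code_for(bases: Iterable[str]) -> str:
    """IUPAC code covering exactly the given set of plain bases."""
    key = frozenset(bases)
    try:
        return SET_TO_CODE[key]
    except KeyError:
        raise ValueError(f"not a valid base set: {sorted(key)}") from None


def compatible(a: str, b: str) -> bool:
    """True when two IUPAC codes share at least one plain base."""
    return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])


def is_degenerate(code: str) -> bool:
    return code not in "ACGT"


def degeneracy_fraction(seq: str) -> float:
    """Fraction of positions carrying a non-ACGT code."""
    if not seq:
        return 0.0
    return sum(1 for c in seq if is_degenerate(c)) / len(seq)


def expand_word(word: str, cap: int = 64) -> list[str] | None:
    """All plain-base words covered by a degenerate word.

    Returns None when the number of expansions would exceed ``cap`` (the
    caller then skips seeding from this word).
    """
    n = 1
    for c in word:
        n *= len(IUPAC_SETS[c])
        if n > cap:
            return None
    words = [""]
    for c in word:
        bases = IUPAC_SETS[c]
        words = [w + b for w in words for b in sorted(bases)]
    return words


def validate_sequence(seq: str, alphabet: frozenset[str], what: str = "sequence") -> None:
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"{what} contains illegal characters: {sorted(bad)}")
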