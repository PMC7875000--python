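"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through different algorithms than the
package: a full-matrix affine-gap Smith-Waterman scan (no seeding, no
windows), a plain quadratic Needleman-Wunsch, and an exhaustive enumeration
of locus chainings.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence

import numpy as np
from numba import njit

NEG = -1e9


@njit(cache=True)
def _gotoh_local_fill(tq, qq, match, mismatch, gap_open, gap_extend,
                      H, E, F, ptr, pE, pF):
    n = tq.shape[0]
    m = qq.shape[0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                pE[i, j] = 1
            else:
                E[i, j] = e_ext
                pE[i, j] = 0
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                pF[i, j] = 1
            else:
                F[i, j] = f_ext
                pF[i, j] = 0
            sub = match if tq[i - 1] == qq[j - 1] else mismatch
            diag = H[i - 1, j - 1] + sub
            best = 0.0
            p = 0
            if diag > best:
                best = diag
                p = 1
            if E[i, j] > best:
                best = E[i, j]
                p = 2
            if F[i, j] > best:
                best = F[i, j]
                p = 3
            # tie preference mirrors the order: diag, then E, then F
            if p == 0 and diag == best and best > 0:
                p = 1
            H[i, j] = best
            ptr[i, j] = p


def sw_local_oracle(target: str, query: str, match: float = 2.0,
                    mismatch: float = -3.0, gap_open: float = -5.0,
                    gap_extend: float = -2.0):
    """Full Gotoh local alignment of query vs target over the whole matrix.

    Returns (score, (t_start, t_end), (q_start, q_end), identity) of the
    best local alignment, or None if the best score is <= 0.  Identity is
    matches / alignment columns (internal gaps included).
    """
    n, m = len(target), len(query)
    tq = np.frombuffer(target.encode(), dtype=np.uint8)
    qq = np.frombuffer(query.encode(), dtype=np.uint8)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in target (consumes query)
    F = np.full((n + 1, m + 1), NEG)  # gap in query (consumes target)
    # pointers: 0 stop, 1 diag, 2 from E, 3 from F
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    pE = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 = opened here
    pF = np.zeros((n + 1, m + 1), dtype=np.int8)
    _gotoh_local_fill(tq, qq, match, mismatch, gap_open, gap_extend,
                      H, E, F, ptr, pE, pF)
    score = float(H.max())
    if score <= 0:
        return None
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    t_end, q_end = int(i), int(j)
    matches = columns = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if target[i - 1] == query[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            opened = pE[i, j]
            j -= 1
            if opened:
                state = "H"
        else:
            columns += 1
            opened = pF[i, j]
            i -= 1
            if opened:
                state = "H"
    t_start, q_start = int(i), int(j)
    identity = matches / columns if columns else 0.0
    return score, (t_start, t_end), (q_start, q_end), identity


def nw_global_oracle(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
                     gap_open: float = -10.0, gap_extend: float = -6.0):
    """Plain affine-gap global alignment; returns (score, identity).

    Identity is matches / columns with terminal gap columns excluded,
    mirroring the package's definition but computed by an independent DP.
    """
    n, m = len(a), len(b)
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    pE = np.zeros((n + 1, m + 1), dtype=np.int8)
    pF = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = gap_open + gap_extend * (j - 1)
        H[0, j] = E[0, j]
        ptr[0, j] = 2
        pE[0, j] = 1 if j == 1 else 0
    for i in range(1, n + 1):
        F[i, 0] = gap_open + gap_extend * (i - 1)
        H[i, 0] = F[i, 0]
        ptr[i, 0] = 3
        pF[i, 0] = 1 if i == 1 else 0
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            E[i, j] = max(e_open, e_ext)
            pE[i, j] = 1 if e_open >= e_ext else 0
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            F[i, j] = max(f_open, f_ext)
            pF[i, j] = 1 if f_open >= f_ext else 0
            diag = H[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            H[i, j] = max(diag, E[i, j], F[i, j])
            if H[i, j] == diag:
                ptr[i, j] = 1
            elif H[i, j] == E[i, j]:
                ptr[i, j] = 2
            else:
                ptr[i, j] = 3
    # traceback, recording column types
    cols: list[tuple[str, bool]] = []  # (kind, is_match)
    i, j = n, m
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            p = ptr[i, j]
            if p == 1:
                cols.append(("sub", a[i - 1] == b[j - 1]))
                i, j = i - 1, j - 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols.append(("gap", False))
            opened = pE[i, j]
            j -= 1
            if opened:
                state = "H"
        else:
            cols.append(("gap", False))
            opened = pF[i, j]
            i -= 1
            if opened:
                state = "H"
    cols.reverse()
    # strip terminal gap runs
    lo = 0
    while lo < len(cols) and cols[lo][0] == "gap":
        lo += 1
    hi = len(cols)
    while hi > lo and cols[hi - 1][0] == "gap":
        hi -= 1
    core = cols[lo:hi]
    identity = (sum(1 for _k, is_m in core if is_m) / len(core)) if core else 0.0
    return float(H[n, m]), identity


def max_locus_chains(hits: Sequence, max_gap: int,
                     require_colinear: bool = True) -> int:
    """Exhaustive maximum number of disjoint complete (2,3,4) chains.

    ``hits`` are (start, end, exon_label, strand) tuples on one contig and
    one class.  Enumerates every family of disjoint valid triples.
    """
    def valid(triple) -> bool:
        strands = {h[3] for h in triple}
        if len(strands) > 1:
            return False
        strand = strands.pop()
        order = (2, 3, 4) if (strand == "+" or not require_colinear) else (4, 3, 2)
        if not require_colinear:
            # any left-to-right label arrangement allowed
            arranged = sorted(triple, key=lambda h: h[0])
            if {h[2] for h in arranged} != {2, 3, 4}:
                return False
        else:
            arranged = sorted(triple, key=lambda h: h[0])
            if tuple(h[2] for h in arranged) != order:
                return False
        for a, b in zip(arranged, arranged[1:]):
            gap = b[0] - a[1]
            if not 0 <= gap <= max_gap:
                return False
        return True

    triples = [t for t in itertools.combinations(range(len(hits)), 3)
               if valid([hits[i] for i in t])]

    best = 0
    def recurse(chosen_idx: set, start: int, count: int) -> None:
        nonlocal best
        best = max(best, count)
        for t in range(start, len(triples)):
            tri = triples[t]
            if chosen_idx.isdisjoint(tri):
                recurse(chosen_idx | set(tri), t + 1, count + 1)

    recurse(set(), 0, 0)
    return best


def brute_overlap_components(spans: Sequence[tuple[int, int]],
                             frac: float = 0.5) -> list[set[int]]:
    """Connected components under reciprocal-overlap >= frac (brute force)."""
    n = len(spans)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = spans[i], spans[j]
            ov = max(0, min(e1, e2) - max(s1, s2))
            if ov >= frac * (e1 - s1) and ov >= frac * (e2 - s2):
                adj[i].add(j)
                adj[j].add(i)
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(comp)
    return comps
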