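"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (full dynamic programming, exhaustive
enumeration, direct pair counting) and shares no code path with the package
beyond static data tables.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def smith_waterman_score(a: str, b: str, gap_open: float = -11,
                         gap_extend: float = -1) -> float:
    """Affine-gap local alignment score (Gotoh), BLOSUM62, pure Python."""
    n, m = len(a), len(b)
    neg = float("-inf")
    best = 0.0
    h_prev = [0.0] * (m + 1)
    e_prev = [neg] * (m + 1)
    for i in range(1, n + 1):
        h_cur = [0.0] * (m + 1)
        e_cur = [neg] * (m + 1)
        f = neg
        for j in range(1, m + 1):
            e_cur[j] = max(h_prev[j] + gap_open, e_prev[j] + gap_extend)
            f = max(h_cur[j - 1] + gap_open, f + gap_extend)
            sub = BLOSUM62[a[i - 1], b[j - 1]]
            h = max(0.0, h_prev[j - 1] + sub, e_cur[j], f)
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, e_prev = h_cur, e_cur
    return best


def codon_walk_orfs(region: str, min_len_aa: int) -> set[tuple]:
    """All ATG..stop ORFs >= min_len_aa codons on both strands.

    Returns {(start, end, strand)} in forward-region coordinates, end
    inclusive of the stop codon; same-frame overlaps reduced to the ORF
    with the earliest ATG after the previous stop.
    """
    stops = {"TAA", "TAG", "TGA"}
    out: set[tuple] = set()
    for strand in "+-":
        seq = region if strand == "+" else revcomp(region)
        n = len(seq)
        for frame in range(3):
            atg = None
            for p in range(frame, n - 2, 3):
                codon = seq[p : p + 3]
                if codon in stops:
                    if atg is not None and (p - atg) // 3 >= min_len_aa:
                        s, e = atg, p + 3
                        if strand == "-":
                            s, e = n - e, n - s
                        out.add((s, e, strand))
                    atg = None
                elif codon == "ATG" and atg is None:
                    atg = p
    return out


def exact_repeat_pairs(
    seq: str, min_len: int, min_internal: int, max_element: int
) -> set[tuple[int, int, int]]:
    """Maximal exact direct-repeat pairs via exhaustive diagonal scan.

    Returns {(start, repeat_len, distance)} for every maximal run of
    seq[i] == seq[i+d] of length >= min_len whose geometry satisfies the
    element constraints.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    found = set()
    for d in range(min_len + min_internal, min(max_element, n)):
        eq = arr[: n - d] == arr[d:]
        if not eq.any():
            continue
        # maximal runs of True
        idx = np.flatnonzero(eq)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            if len(run) < min_len:
                continue
            length = len(run)
            gap = d - length
            if gap < min_internal or length + d > max_element:
                continue
            found.add((int(run[0]), length, d))
    return found


def brute_tsd(left: str, right: str, lo: int, hi: int) -> str:
    """Longest suffix-of-left == prefix-of-right with length in [lo, hi]."""
    best = ""
    for length in range(lo, hi + 1):
        if length <= len(left) and length <= len(right):
            if left[-length:] == right[:length] and length > len(best):
                best = left[-length:]
    return best


def connected_components(nodes, edges) -> list[frozenset]:
    """BFS connected components from an explicit edge list."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        stack, comp = [n], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def rand_index_pairs(labels_a, labels_b) -> float:
    """Rand index by direct pair counting."""
    n = len(labels_a)
    if n < 2:
        return 1.0
    agree = sum(
        (labels_a[i] == labels_a[j]) == (labels_b[i] == labels_b[j])
        for i, j in combinations(range(n), 2)
    )
    return agree / (n * (n - 1) / 2)


def four_point_topology(d, labels=("A", "B", "C", "D")) -> frozenset:
    """The split of an additive 4-taxon matrix by the four-point condition.

    Returns the pair grouped together, e.g. frozenset({"A","B"}).
    """
    a, b, c, e = labels
    s_ab = d[a][b] + d[c][e]
    s_ac = d[a][c] + d[b][e]
    s_ad = d[a][e] + d[b][c]
    smallest = min(s_ab, s_ac, s_ad)
    if smallest == s_ab:
        return frozenset({a, b})
    if smallest == s_ac:
        return frozenset({a, c})
    return frozenset({a, e})
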