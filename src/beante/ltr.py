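"""De novo LTR retrotransposon candidate discovery.

Finds paired direct repeats (the two LTRs) by exact k-mer seeding on a
shared diagonal, X-drop extension, and a global-alignment identity check,
then automates the manual inspection step: TG...CA terminal dinucleotides,
target-site-duplication search in the flanks, and rejection of tandem
arrays.  Defaults follow the study settings: 50 bp minimum LTR length and
50 bp minimum distance between LTRs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .align import dna_aligner, global_identity, kmer_index
from .classify import find_tsd
from .sequences import GenomeSeq

_CLUSTER_GAP = 100  # max spacing between same-diagonal seeds in one repeat
_XDROP = 12
# stiff mismatch penalty: spurious outward extension into the flanks dies
# quickly, while the 10%-divergence interior still scores forward
_MATCH, _MISMATCH = 1, -3


@dataclass
class DetectConfig:
    min_ltr_len: int = 50
    min_internal: int = 50
    max_element_len: int = 15_000
    min_ltr_identity: float = 80.0
    tsd_len_range: tuple[int, int] = (4, 6)
    tsd_search_window: int = 20
    seed_kmer: int = 15
    max_kmer_occurrences: int = 100
    #: snap repeat boundaries to joint TG...CA + TSD evidence when present;
    #: disable to report pure maximal-extension repeat pairs
    refine_boundaries: bool = True

    def __post_init__(self) -> None:
        if self.min_ltr_len < self.seed_kmer:
            raise ValueError("min_ltr_len must be >= seed_kmer")
        if self.max_element_len <= 2 * self.min_ltr_len + self.min_internal:
            raise ValueError("max_element_len too small for LTR geometry")


@dataclass
class LTRCandidate:
    seq_id: str
    element_span: tuple[int, int]
    left_ltr: tuple[int, int]
    right_ltr: tuple[int, int]
    ltr_identity: float
    tsd: str = ""
    has_tg_ca: bool = False
    status: str | None = None  # accepted / rejected_* once inspected

    @property
    def length(self) -> int:
        return self.element_span[1] - self.element_span[0]


def _extend_diagonal(
    seq: str, lo: int, hi: int, d: int, left_limit: int, right_limit: int
) -> tuple[int, int]:
    """Maximally extend the same-diagonal repeat [lo,hi) vs [lo+d,hi+d).

    Score-based X-drop in both directions, trimmed back to the best-scoring
    endpoints, so the reported repeat cannot be extended without dropping
    the running score (mismatch-dominated flanks are cut off).
    """
    # rightward from hi
    best, score, best_pos = 0, 0, hi
    p = hi
    while p + d < right_limit:
        score += _MATCH if seq[p] == seq[p + d] else _MISMATCH
        p += 1
        if score > best:
            best, best_pos = score, p
        elif best - score > _XDROP:
            break
    hi = best_pos
    # leftward from lo
    best, score, best_pos = 0, 0, lo
    p = lo - 1
    while p >= left_limit:
        score += _MATCH if seq[p] == seq[p + d] else _MISMATCH
        if score > best:
            best, best_pos = score, p
        elif best - score > _XDROP:
            break
        p -= 1
    lo = best_pos
    # trim boundary positions to matches
    while lo < hi and seq[lo] != seq[lo + d]:
        lo += 1
    while hi > lo and seq[hi - 1] != seq[hi - 1 + d]:
        hi -= 1
    return lo, hi


def _refine_with_evidence(
    seq: str, lo: int, hi: int, d: int, cfg: "DetectConfig",
    window: int = 15,
) -> tuple[int, int] | None:
    """Snap repeat-pair outer boundaries to joint TG...CA + TSD evidence.

    Score-based trimming places boundaries only to within a few bp when the
    repeat termini carry mismatches; LTR ends are better defined by the
    terminal dinucleotides together with a flanking duplication.  Both
    pieces of evidence are required, so repeats that are not LTR-like are
    left untouched.
    """
    e0 = hi + d
    best = None
    for dl in range(-window, window + 1):
        s = lo + dl
        # both repeat copies are copies of the same LTR, so the terminal
        # TG must be present at the matching offset in both
        if s < 0 or seq[s : s + 2] != "TG" or seq[s + d : s + d + 2] != "TG":
            continue
        for dr in range(-window, window + 1):
            e = e0 + dr
            if (e > len(seq) or seq[e - 2 : e] != "CA"
                    or seq[e - d - 2 : e - d] != "CA"):
                continue
            lo_t, hi_t = cfg.tsd_len_range
            hi_eff = min(hi_t, s, len(seq) - e)
            if hi_eff < lo_t:
                continue
            left = seq[s - hi_eff : s]
            right = seq[e : e + hi_eff]
            tsd = find_tsd(left, right, (lo_t, hi_eff))
            if not tsd:
                continue
            # longest TSD first: when the duplication itself ends in TG
            # (or starts with CA) the 2-bp-shifted parse carries a
            # truncated TSD, so the longer one marks the real boundary
            key = (len(tsd), -(abs(dl) + abs(dr)))
            if best is None or key > best[0]:
                best = (key, dl, dr)
    if best is None:
        return None
    return best[1], best[2]


def find_direct_repeat_pairs(
    genome: GenomeSeq, cfg: DetectConfig | None = None
) -> list[LTRCandidate]:
    """Report maximal same-strand direct repeat pairs (status unset).

    Each pair has two repeats of length >= ``min_ltr_len`` at identity >=
    ``min_ltr_identity`` separated by an internal region in
    [min_internal, max_element_len - 2*min_ltr_len].  Overlapping candidates
    are resolved greedily by (identity, element length), leftmost on ties.
    """
    cfg = cfg or DetectConfig()
    seq = genome.residues
    k = cfg.seed_kmer
    if len(seq) < 2 * cfg.min_ltr_len + cfg.min_internal:
        raise ValueError("genome shorter than the minimum LTR element")
    index = kmer_index(seq, k, max_occurrences=cfg.max_kmer_occurrences)

    # seed pairs grouped by diagonal (distance between repeat starts)
    diagonals: dict[int, list[int]] = defaultdict(list)
    max_d = cfg.max_element_len - cfg.min_ltr_len
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions) - 1):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if d > max_d:
                    break
                diagonals[d].append(positions[ai])

    raw: list[LTRCandidate] = []
    seen: set[tuple[int, int, int]] = set()
    for d, starts in diagonals.items():
        starts.sort()
        clusters: list[list[int]] = [[starts[0]]]
        for s in starts[1:]:
            if s - clusters[-1][-1] <= _CLUSTER_GAP:
                clusters[-1].append(s)
            else:
                clusters.append([s])
        for cluster in clusters:
            lo, hi = _extend_diagonal(
                seq, cluster[0], cluster[-1] + k, d,
                left_limit=0, right_limit=len(seq) - d,
            )
            length = hi - lo
            gap = d - length
            if length < cfg.min_ltr_len:
                continue
            if gap < cfg.min_internal:
                continue
            if length + d > cfg.max_element_len:
                continue
            key = (lo, hi, d)
            if key in seen:
                continue
            seen.add(key)
            identity = global_identity(seq[lo:hi], seq[lo + d : hi + d])
            if identity < cfg.min_ltr_identity:
                continue
            refined = (
                _refine_with_evidence(seq, lo, hi, d, cfg)
                if cfg.refine_boundaries else None
            )
            if refined is not None:
                dl, dr = refined
                lo2, hi2 = lo + dl, hi + dr
                if (hi2 - lo2 >= cfg.min_ltr_len
                        and d - (hi2 - lo2) >= cfg.min_internal):
                    lo, hi = lo2, hi2
                    identity = global_identity(
                        seq[lo:hi], seq[lo + d : hi + d]
                    )
            raw.append(LTRCandidate(
                seq_id=genome.seq_id,
                element_span=(lo, hi + d),
                left_ltr=(lo, hi),
                right_ltr=(lo + d, hi + d),
                ltr_identity=round(identity, 2),
            ))

    # overlap resolution: best (identity, length) wins, leftmost on ties
    raw.sort(key=lambda c: (-c.ltr_identity, -c.length, c.element_span[0]))
    kept: list[LTRCandidate] = []
    for cand in raw:
        s, e = cand.element_span
        if any(s < k.element_span[1] and k.element_span[0] < e for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: (c.seq_id, c.element_span[0]))
    return kept


def _is_tandem(seq: str, cand: LTRCandidate) -> bool:
    """Tandem-array test: internal region looks like another LTR copy.

    Operationalized as: the best local alignment of the left LTR within the
    internal region scores at least half the LTR length (for identical
    units the score equals the unit length; unrelated sequence stays near
    the random-alignment noise floor).
    """
    internal = seq[cand.left_ltr[1] : cand.right_ltr[0]]
    ltr = seq[cand.left_ltr[0] : cand.left_ltr[1]]
    if not internal or not ltr:
        return False
    aligner = dna_aligner()
    score = aligner.score(internal, ltr)
    return score >= 0.5 * len(ltr)


def inspect_candidate(
    genome: GenomeSeq, cand: LTRCandidate, cfg: DetectConfig | None = None
) -> LTRCandidate:
    """Automated boundary/TSD/structure inspection; sets ``status``.

    Boundaries may shift by up to 3 bp where that improves the joint
    TG...CA and TSD evidence.  Accepted requires a TSD in range and a
    non-tandem internal region.
    """
    cfg = cfg or DetectConfig()
    seq = genome.residues
    s0, e0 = cand.element_span
    if not (0 <= s0 < e0 <= len(seq)):
        raise ValueError("candidate span outside genome")
    w = cfg.tsd_search_window
    best = None
    for dl in range(-3, 4):
        for dr in range(-3, 4):
            s, e = s0 + dl, e0 + dr
            if s < 0 or e > len(seq) or s >= e:
                continue
            has_tg_ca = seq[s : s + 2] == "TG" and seq[e - 2 : e] == "CA"
            left = seq[max(0, s - w) : s]
            right = seq[e : e + w]
            lo_t, hi_t = cfg.tsd_len_range
            hi_eff = min(hi_t, len(left), len(right))
            tsd = (
                find_tsd(left, right, (lo_t, hi_eff))
                if hi_eff >= lo_t else ""
            )
            score = (2 if tsd else 0) + (1 if has_tg_ca else 0)
            # at equal evidence prefer the smaller shift: a 1-bp-shifted
            # boundary with a chance longer duplication must not outrank
            # the unshifted boundary with the genuine TSD
            key = (score, -(abs(dl) + abs(dr)), len(tsd), -dl, -dr)
            if best is None or key > best[0]:
                best = (key, s, e, tsd, has_tg_ca)
    assert best is not None
    _, s, e, tsd, has_tg_ca = best
    # inner LTR edges stay anchored; only the outer edges move with the shift
    out = replace(
        cand,
        element_span=(s, e),
        left_ltr=(s, cand.left_ltr[1]),
        right_ltr=(cand.right_ltr[0], e),
        tsd=tsd,
        has_tg_ca=has_tg_ca,
    )
    if (out.left_ltr[1] - out.left_ltr[0] < cfg.min_ltr_len
            or out.right_ltr[1] - out.right_ltr[0] < cfg.min_ltr_len
            or out.right_ltr[0] - out.left_ltr[1] < cfg.min_internal):
        out.status = "rejected_structure"
    elif _is_tandem(seq, out):
        out.status = "rejected_tandem"
    elif not tsd:
        out.status = "rejected_no_tsd"
    else:
        out.status = "accepted"
    return out


def inspect_all(
    genome: GenomeSeq, cands: Sequence[LTRCandidate],
    cfg: DetectConfig | None = None,
) -> list[LTRCandidate]:
    return [inspect_candidate(genome, c, cfg) for c in cands]


def ltr_identity_report(cands: Sequence[LTRCandidate]) -> pd.DataFrame:
    """Tabulate LTR identity; 100%-identical pairs flag recent insertions."""
    rows = []
    for c in cands:
        if c.status not in (None, "accepted"):
            continue
        rows.append(dict(
            seq_id=c.seq_id,
            start=c.element_span[0],
            end=c.element_span[1],
            ltr_identity=c.ltr_identity,
            recent_insertion=c.ltr_identity >= 100.0,
        ))
    return pd.DataFrame(
        rows, columns=["seq_id", "start", "end", "ltr_identity",
                       "recent_insertion"],
    )
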