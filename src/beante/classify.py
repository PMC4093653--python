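"""Superfamily classification from terminal motifs, TIRs, TSDs and polyA.

Codifies the manual-inspection rules used for DNA transposons and non-LTR
retroelements: CACTA terminal motifs with a 2-3 bp TSD, terminal inverted
repeats with superfamily-diagnostic TSD lengths (hAT 8 bp, MULE 9-11 bp,
PIF/Harbinger 3 bp), polyA tails plus long variable TSDs for LINEs/SINEs,
and homology-only classification for Helitrons (which leave no TSD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .sequences import GenomeSeq, revcomp

logger = logging.getLogger(__name__)

CLASS1 = {"Ty1-copia", "Ty3-gypsy", "LTR-unclassified", "LINE", "SINE"}


@dataclass(frozen=True)
class SuperfamilyRule:
    superfamily: str
    five_prime_motif: str = ""
    three_prime_motif: str = ""
    tir_min_len: int = 0
    tsd_len_range: tuple[int, int] = (0, 0)
    requires_polya: bool = False
    max_len: int | None = None


#: one rule per supported superfamily (order encodes structural precedence)
RULES: dict[str, SuperfamilyRule] = {
    "CACTA": SuperfamilyRule(
        "CACTA", five_prime_motif="CACTA", three_prime_motif="ATGTG",
        tsd_len_range=(2, 3),
    ),
    "MULE": SuperfamilyRule("MULE", tir_min_len=40, tsd_len_range=(9, 11)),
    "hAT": SuperfamilyRule("hAT", tir_min_len=10, tsd_len_range=(8, 8)),
    "PIF/Harbinger": SuperfamilyRule(
        "PIF/Harbinger", tir_min_len=10, tsd_len_range=(3, 3)
    ),
    "LINE": SuperfamilyRule(
        "LINE", requires_polya=True, tsd_len_range=(5, 29)
    ),
    "SINE": SuperfamilyRule(
        "SINE", requires_polya=True, tsd_len_range=(5, 29), max_len=700
    ),
    "Helitron": SuperfamilyRule("Helitron"),  # homology-only, no TSD
}


def rules_with_cacta_motif(three_prime: str) -> dict[str, SuperfamilyRule]:
    """Rule table with a configurable CACTA 3' motif (literal vs revcomp)."""
    out = dict(RULES)
    out["CACTA"] = SuperfamilyRule(
        "CACTA", five_prime_motif="CACTA", three_prime_motif=three_prime,
        tsd_len_range=(2, 3),
    )
    return out


@dataclass
class ClassifiedTE:
    element_id: str
    seq_id: str
    span: tuple[int, int]
    strand: str
    te_class: int
    superfamily: str
    tsd: str = ""
    evidence: set[str] = field(default_factory=set)
    complete: bool = False

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


def find_tsd(
    left_flank: str, right_flank: str, len_range: tuple[int, int]
) -> str:
    """Longest duplication adjacent to both element boundaries.

    The TSD must be a suffix of the left flank and a prefix of the right
    flank with length within ``len_range``; returns "" when none exists.
    """
    lo, hi = len_range
    if lo < 1:
        raise ValueError("len_range minimum must be >= 1")
    if len(left_flank) < hi or len(right_flank) < hi:
        raise ValueError("flank windows shorter than the maximum TSD length")
    for length in range(hi, lo - 1, -1):
        if left_flank[-length:] == right_flank[:length]:
            return left_flank[-length:]
    return ""


def _tsd_at(seq: str, start: int, end: int,
            len_range: tuple[int, int]) -> str:
    lo, hi = len_range
    hi = min(hi, start, len(seq) - end)
    if hi < lo:
        return ""
    return find_tsd(seq[start - hi : start], seq[end : end + hi], (lo, hi))


def _tir_identity(seq: str, start: int, end: int, tir_len: int) -> float:
    """Positionwise identity of the two ends read as an inverted repeat."""
    if end - start < 2 * tir_len:
        return 0.0
    left = seq[start : start + tir_len]
    right = revcomp(seq[end - tir_len : end])
    matches = sum(1 for a, b in zip(left, right) if a == b)
    return matches / tir_len


def _polya_run_ends(seq: str, lo: int, hi: int, base: str = "A",
                    min_run: int = 10) -> list[int]:
    """End positions (exclusive) of >=min_run homopolymer runs in [lo,hi)."""
    ends = []
    run = 0
    for i in range(max(0, lo - min_run), min(len(seq), hi + min_run)):
        if seq[i] == base:
            run += 1
        else:
            if run >= min_run and lo <= i <= hi:
                ends.append(i)
            run = 0
    if run >= min_run:
        i = min(len(seq), hi + min_run)
        if lo <= i <= hi:
            ends.append(i)
    return ends


def _polya_run_starts(seq: str, lo: int, hi: int, base: str = "T",
                      min_run: int = 10) -> list[int]:
    starts = []
    run = 0
    limit = min(len(seq), hi + min_run)
    for i in range(limit - 1, max(0, lo - min_run) - 1, -1):
        if seq[i] == base:
            run += 1
        else:
            if run >= min_run and lo <= i + 1 <= hi:
                starts.append(i + 1)
            run = 0
    if run >= min_run and lo <= max(0, lo - min_run) <= hi:
        starts.append(max(0, lo - min_run))
    return starts


@dataclass
class _StructMatch:
    superfamily: str
    span: tuple[int, int]
    strand: str
    tsd: str
    evidence: set[str]
    tier: int          # lower is stronger (motif < TIR < polyA)
    quality: tuple     # within-tier ranking


def _motif_match(
    seq: str, region: tuple[int, int], rule: SuperfamilyRule, slide: int
) -> _StructMatch | None:
    s0, e0 = region
    five, three = rule.five_prime_motif, rule.three_prime_motif
    best = None
    for strand in "+-":
        if strand == "+":
            lmot, rmot = five, three
        else:
            lmot, rmot = revcomp(three), revcomp(five)
        lpos = [
            p for p in range(max(0, s0 - slide), s0 + slide + 1)
            if seq[p : p + len(lmot)] == lmot
        ]
        rpos = [
            q for q in range(max(len(rmot), e0 - slide),
                             min(len(seq), e0 + slide) + 1)
            if seq[q - len(rmot) : q] == rmot
        ]
        for p in lpos:
            for q in rpos:
                if q - p < 2 * len(lmot) + 10:
                    continue
                tsd = _tsd_at(seq, p, q, rule.tsd_len_range)
                quality = (1 if tsd else 0, len(tsd),
                           -(abs(p - s0) + abs(q - e0)))
                cand = _StructMatch(
                    rule.superfamily, (p, q), strand, tsd,
                    {"terminal_motif"} | ({"tsd"} if tsd else set()),
                    tier=0, quality=quality,
                )
                if best is None or cand.quality > best.quality:
                    best = cand
    return best


def _tir_match(
    seq: str, region: tuple[int, int], rule: SuperfamilyRule, slide: int,
    min_identity: float = 0.8,
) -> _StructMatch | None:
    s0, e0 = region
    best = None
    for p in range(max(0, s0 - slide), s0 + slide + 1):
        for q in range(e0 - slide, min(len(seq), e0 + slide) + 1):
            if q - p < 2 * rule.tir_min_len + 10:
                continue
            tsd = _tsd_at(seq, p, q, rule.tsd_len_range)
            if not tsd:
                continue
            ident = _tir_identity(seq, p, q, rule.tir_min_len)
            if ident < min_identity:
                continue
            quality = (len(tsd), ident, -(abs(p - s0) + abs(q - e0)))
            cand = _StructMatch(
                rule.superfamily, (p, q), "+", tsd, {"tir", "tsd"},
                tier=1, quality=quality,
            )
            if best is None or cand.quality > best.quality:
                best = cand
    return best


def _polya_match(
    seq: str, region: tuple[int, int], rule: SuperfamilyRule, slide: int
) -> _StructMatch | None:
    s0, e0 = region
    best = None
    # plus strand: polyA tail at the 3' (right) end
    for e in _polya_run_ends(seq, e0 - slide, e0 + slide):
        for p in range(max(0, s0 - slide), s0 + slide + 1):
            if e - p < 50:
                continue
            tsd = _tsd_at(seq, p, e, rule.tsd_len_range)
            if not tsd:
                continue
            quality = (len(tsd), -(abs(p - s0) + abs(e - e0)))
            cand = _StructMatch(
                rule.superfamily, (p, e), "+", tsd, {"polyA", "tsd"},
                tier=2, quality=quality,
            )
            if best is None or cand.quality > best.quality:
                best = cand
    # minus strand: polyT head at the left end
    for s in _polya_run_starts(seq, s0 - slide, s0 + slide):
        for q in range(e0 - slide, min(len(seq), e0 + slide) + 1):
            if q - s < 50:
                continue
            tsd = _tsd_at(seq, s, q, rule.tsd_len_range)
            if not tsd:
                continue
            quality = (len(tsd), -(abs(s - s0) + abs(q - e0)))
            cand = _StructMatch(
                rule.superfamily, (s, q), "-", tsd, {"polyA", "tsd"},
                tier=2, quality=quality,
            )
            if best is None or cand.quality > best.quality:
                best = cand
    return best


def classify_candidate(
    genome: GenomeSeq,
    region: tuple[int, int],
    hits: Sequence["DomainHit"] = (),  # noqa: F821 - forward ref
    rules: Mapping[str, SuperfamilyRule] | None = None,
    query_superfamilies: Mapping[str, str] | None = None,
    slide: int = 50,
    element_id: str = "",
) -> ClassifiedTE:
    """Assign a superfamily to a candidate region.

    The region's ends may each move by up to ``slide`` bp to maximize joint
    motif/TIR/polyA + TSD evidence; structural evidence outranks homology
    alone; regions with neither become "unclassified".
    """
    rules = rules or RULES
    seq = genome.residues
    s0, e0 = region
    if not (0 <= s0 < e0 <= len(seq)):
        raise ValueError("region outside genome")

    hit_sfs: list[str] = []
    hit_strand = None
    for h in hits:
        hs, he = h.genome_span
        if hs < e0 and s0 < he:
            sf = (query_superfamilies or {}).get(h.query_id, h.query_id)
            hit_sfs.append(sf)
            if hit_strand is None:
                hit_strand = h.strand

    matches: list[_StructMatch] = []
    for rule in rules.values():
        if rule.five_prime_motif:
            m = _motif_match(seq, region, rule, slide)
        elif rule.tir_min_len:
            m = _tir_match(seq, region, rule, slide)
        elif rule.requires_polya:
            m = _polya_match(seq, region, rule, slide)
        else:
            m = None
        if m is not None and m.tsd:
            matches.append(m)

    if matches:
        best_tier = min(m.tier for m in matches)
        top = [m for m in matches if m.tier == best_tier]
        top.sort(key=lambda m: m.quality, reverse=True)
        distinct = {m.superfamily for m in top}
        # LINE vs SINE share the polyA rule: resolve by homology and length
        if distinct == {"LINE", "SINE"}:
            has_rt = "LINE" in hit_sfs
            length = top[0].span[1] - top[0].span[0]
            sine_max = rules["SINE"].max_len or 700
            pick = "LINE" if (has_rt or length > sine_max) else "SINE"
            top = [m for m in top if m.superfamily == pick]
            distinct = {pick}
        if len(distinct) > 1 and len({m.quality for m in top[:2]}) == 1:
            logger.error(
                "ambiguous structural classification at %s:%s-%s: %s",
                genome.seq_id, s0, e0, sorted(distinct),
            )
        else:
            m = top[0]
            evidence = set(m.evidence)
            if m.superfamily in hit_sfs:
                evidence.add("domain_homology")
            strand = m.strand if m.strand != "+" or m.tier != 1 else (
                hit_strand or "+"
            )
            return ClassifiedTE(
                element_id=element_id, seq_id=genome.seq_id, span=m.span,
                strand=strand,
                te_class=1 if m.superfamily in CLASS1 else 2,
                superfamily=m.superfamily, tsd=m.tsd, evidence=evidence,
                complete=True,
            )

    if hit_sfs:
        counts: dict[str, int] = {}
        for sf in hit_sfs:
            counts[sf] = counts.get(sf, 0) + 1
        sf = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        return ClassifiedTE(
            element_id=element_id, seq_id=genome.seq_id, span=(s0, e0),
            strand=hit_strand or "+",
            te_class=1 if sf in CLASS1 else 2,
            superfamily=sf, tsd="", evidence={"domain_homology"},
            complete=False,
        )

    return ClassifiedTE(
        element_id=element_id, seq_id=genome.seq_id, span=(s0, e0),
        strand="+", te_class=2, superfamily="unclassified",
        tsd="", evidence=set(), complete=False,
    )


# ---------------------------------------------------------------------------
# locating element boundaries around a domain hit (flank scanning)

def locate_element(
    genome: GenomeSeq,
    hit: "DomainHit",  # noqa: F821
    query_superfamilies: Mapping[str, str],
    rules: Mapping[str, SuperfamilyRule] | None = None,
) -> ClassifiedTE:
    """Search a hit's flank window for rule-consistent element boundaries.

    Used by the pipeline for homology-discovered elements where only the
    coding region is known; returns a (possibly incomplete) classification.
    """
    rules = rules or RULES
    seq = genome.residues
    sf = query_superfamilies.get(hit.query_id, hit.query_id)
    fs, fe = hit.flank_span
    hs, he = hit.genome_span
    rule = rules.get(sf)

    if rule and rule.five_prime_motif:
        lmot = rule.five_prime_motif if hit.strand == "+" else revcomp(
            rule.three_prime_motif
        )
        rmot = rule.three_prime_motif if hit.strand == "+" else revcomp(
            rule.five_prime_motif
        )
        lpos = _find_all(seq, lmot, fs, hs)
        rpos = [q + len(rmot) for q in _find_all(seq, rmot, he, fe)]
        best = None
        # longest TSD outranks motif proximity: short chance duplications
        # (2-3 bp for CACTA) readily validate chance inner motif copies
        for p in lpos:
            for q in rpos:
                tsd = _tsd_at(seq, p, q, rule.tsd_len_range)
                if not tsd:
                    continue
                key = (len(tsd), -(q - p))
                if best is None or key > best[0]:
                    best = (key, p, q, tsd)
        if best:
            _key, p, q, tsd = best
            return ClassifiedTE(
                element_id="", seq_id=genome.seq_id, span=(p, q),
                strand=hit.strand, te_class=2, superfamily=sf, tsd=tsd,
                evidence={"terminal_motif", "tsd", "domain_homology"},
                complete=True,
            )

    if rule and rule.tir_min_len:
        found = _find_tir_element(
            seq, fs, fe, rule, must_contain=(hs, he), max_len=10_000
        )
        if found:
            p, q, tsd = found
            return ClassifiedTE(
                element_id="", seq_id=genome.seq_id, span=(p, q),
                strand=hit.strand, te_class=2, superfamily=sf, tsd=tsd,
                evidence={"tir", "tsd", "domain_homology"}, complete=True,
            )

    if rule and rule.requires_polya:
        found = _locate_polya_element(seq, fs, fe, (hs, he), rule,
                                      hit.strand)
        if found:
            p, q, tsd = found
            return ClassifiedTE(
                element_id="", seq_id=genome.seq_id, span=(p, q),
                strand=hit.strand, te_class=1, superfamily=sf, tsd=tsd,
                evidence={"polyA", "tsd", "domain_homology"}, complete=True,
            )

    return ClassifiedTE(
        element_id="", seq_id=genome.seq_id, span=(hs, he),
        strand=hit.strand,
        te_class=1 if sf in CLASS1 else 2,
        superfamily=sf, tsd="", evidence={"domain_homology"},
        complete=False,
    )


def _find_all(seq: str, motif: str, lo: int, hi: int) -> list[int]:
    out = []
    i = seq.find(motif, lo)
    while i != -1 and i <= hi:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def _locate_polya_element(
    seq: str, fs: int, fe: int, hit_span: tuple[int, int],
    rule: SuperfamilyRule, strand: str,
) -> tuple[int, int, str] | None:
    hs, he = hit_span
    lo_t, hi_t = rule.tsd_len_range
    if strand == "+":
        # polyA tail ends the element; the TSD right copy starts there
        for e in _polya_run_ends(seq, he, fe)[:3]:
            for length in range(min(hi_t, len(seq) - e), lo_t - 1, -1):
                probe = seq[e : e + length]
                occs = _find_all(seq, probe, fs, hs - length)
                if occs:
                    # rightmost left copy gives the smallest element
                    return occs[-1] + length, e, probe
    else:
        # minus strand: polyT head starts the element, TSD right copy at end
        heads = _polya_run_starts(seq, fs, hs)
        for s in sorted(heads, reverse=True)[:3]:
            for length in range(min(hi_t, s), lo_t - 1, -1):
                probe = seq[s - length : s]
                occs = _find_all(seq, probe, he, fe - length)
                if occs:
                    return s, occs[0], probe
    return None


def _find_tir_element(
    seq: str, fs: int, fe: int, rule: SuperfamilyRule,
    must_contain: tuple[int, int], max_len: int = 10_000,
    seed_k: int = 8, slide: int | None = None,
) -> tuple[int, int, str] | None:
    """TIR+TSD boundaries enclosing a hit within its flank window.

    Inverted-repeat seeds anchor approximate ends; boundaries then shift
    to the position where an exact TSD in the rule's range flanks a TIR
    of sufficient identity.  The shift window covers a full TIR length:
    an exact-match seed can sit anywhere inside a diverged TIR.
    """
    if slide is None:
        slide = rule.tir_min_len + 12
    hs, he = must_contain
    fe = min(fe, len(seq))
    index: dict[str, list[int]] = {}
    for i in range(fs, max(fs, hs - seed_k) + 1):
        index.setdefault(seq[i : i + seed_k], []).append(i)
    best = None
    for j in range(he, fe - seed_k + 1):
        probe = revcomp(seq[j : j + seed_k])
        for i in index.get(probe, ()):
            s2, e2, _tir = _extend_inverted(seq, i, j + seed_k, seed_k)
            if e2 - s2 > max_len or not (s2 <= hs and he <= e2):
                continue
            for ds in range(-slide, slide + 1):
                for de in range(-slide, slide + 1):
                    p, q = s2 + ds, e2 + de
                    if p < 0 or q > len(seq):
                        continue
                    if q - p < 2 * rule.tir_min_len + 10:
                        continue
                    tsd = _tsd_at(seq, p, q, rule.tsd_len_range)
                    if not tsd:
                        continue
                    ident = _tir_identity(seq, p, q, rule.tir_min_len)
                    if ident < 0.8:
                        continue
                    key = (len(tsd), ident, -(abs(ds) + abs(de)))
                    if best is None or key > best[0]:
                        best = (key, p, q, tsd)
    if best is None:
        return None
    _key, p, q, tsd = best
    return p, q, tsd


# ---------------------------------------------------------------------------
# MITE-style short TIR element discovery

def _extend_inverted(seq: str, i: int, e: int, k: int) -> tuple[int, int, int]:
    """Extend an exact inverted-repeat seed outward; returns (i, e, tir_len)."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "X"}
    # outward
    while i > 0 and e < len(seq) and comp.get(seq[i - 1]) == seq[e]:
        i -= 1
        e += 1
    # inward
    tir = k
    while (i + tir < e - tir
           and comp.get(seq[i + tir]) == seq[e - tir - 1]):
        tir += 1
    return i, e, tir


def find_mite_like(
    genome: GenomeSeq,
    max_len: int = 2000,
    tir_min_len: int = 12,
    seed_k: int = 10,
    min_tsd_len: int = 3,
    rules: Mapping[str, SuperfamilyRule] | None = None,
) -> list[tuple[int, int]]:
    """Short TIR+TSD elements (MITE candidates), deduplicated by span.

    Reports intervals whose ends form an inverted repeat of at least
    ``tir_min_len`` and which are flanked by a TSD with length in any
    class-2 rule's range.  Because de novo discovery has no transposase
    support, the defaults are stricter than the per-superfamily
    classification rules: chance inverted 10-mers are common in megabase
    sequence, so a 12 bp TIR and a >=3 bp TSD are required (2-bp TSDs are
    accepted only together with a CACTA terminal motif, via the
    classification path).
    """
    rules = rules or RULES
    seq = genome.residues
    tsd_lengths = sorted(
        {
            length
            for rule in rules.values()
            if rule.tir_min_len or rule.five_prime_motif
            for length in range(rule.tsd_len_range[0],
                                rule.tsd_len_range[1] + 1)
            if length >= min_tsd_len
        },
        reverse=True,
    )
    from .align import kmer_index

    index = kmer_index(seq, seed_k, max_occurrences=100)
    found: dict[tuple[int, int], tuple[int, int]] = {}
    for j in range(len(seq) - seed_k + 1):
        probe = revcomp(seq[j : j + seed_k])
        for i in index.get(probe, ()):
            e = j + seed_k
            if i >= j or e - i > max_len or e - i < 2 * tir_min_len + 10:
                continue
            s2, e2, tir = _extend_inverted(seq, i, e, seed_k)
            if tir < tir_min_len or e2 - s2 > max_len:
                continue
            tsd = ""
            for length in tsd_lengths:
                if s2 >= length and e2 + length <= len(seq):
                    if seq[s2 - length : s2] == seq[e2 : e2 + length]:
                        tsd = seq[s2 - length : s2]
                        break
            if not tsd or len(set(tsd)) == 1:
                continue
            found[(s2, e2)] = (s2, e2)
    # dedupe: drop spans contained in a wider reported span
    spans = sorted(found)
    kept: list[tuple[int, int]] = []
    for s, e in spans:
        if any(ks <= s and e <= ke for ks, ke in kept):
            continue
        kept = [k for k in kept if not (s <= k[0] and k[1] <= e)]
        kept.append((s, e))
    return sorted(kept)
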