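"""Family clustering, representative library, and chromosomal distribution.

Elements sharing more than 70% sequence similarity are single-linkage
clustered into families (the classic 80-80-80 tradition's similarity leg);
each family is represented in the library by its intact or longest member.
The library summary follows the study's Table-1 layout: class 1 (Ty1-copia,
Ty3-gypsy, unclassified LTR, LINE, SINE), class 2 (CACTA, hAT, MULE,
Helitron, PIF/Harbinger), plus globally unclassified repeats; all totals
are computed, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .classify import ClassifiedTE
from .sequences import GenomeSeq, revcomp

#: three-letter family-id prefixes (Wicker-style codes)
FAMILY_PREFIX = {
    "Ty1-copia": "RLC", "Ty3-gypsy": "RLG", "LTR-unclassified": "RLX",
    "LINE": "RIL", "SINE": "RSX", "CACTA": "DTC", "hAT": "DTA",
    "MULE": "DTM", "PIF/Harbinger": "DTH", "Helitron": "DHH",
    "unclassified": "XXX",
}

#: RepeatMasker-compatible Class/Superfamily header suffixes
RM_CLASS = {
    "Ty1-copia": "LTR/Copia", "Ty3-gypsy": "LTR/Gypsy",
    "LTR-unclassified": "LTR/Unknown", "LINE": "LINE", "SINE": "SINE",
    "CACTA": "DNA/CACTA", "hAT": "DNA/hAT", "MULE": "DNA/MULE",
    "PIF/Harbinger": "DNA/PIF-Harbinger", "Helitron": "RC/Helitron",
    "unclassified": "Unknown",
}

#: Table-1 category layout
CLASS1_CATEGORIES = ("Ty1-copia", "Ty3-gypsy", "LTR-unclassified",
                     "LINE", "SINE")
CLASS2_CATEGORIES = ("CACTA", "hAT", "MULE", "Helitron", "PIF/Harbinger")
ALL_CATEGORIES = CLASS1_CATEGORIES + CLASS2_CATEGORIES + ("unclassified",)


@dataclass
class TEFamily:
    family_id: str
    superfamily: str
    member_ids: frozenset[str]
    representative_id: str = ""

    def __post_init__(self) -> None:
        if self.representative_id and (
                self.representative_id not in self.member_ids):
            raise ValueError("representative must be a family member")


@dataclass
class TELibrary:
    records: list[tuple[str, str]]  # (header, sequence)
    summary: dict[str, int]         # per-category family counts

    @property
    def total_bp(self) -> int:
        return sum(len(seq) for _h, seq in self.records)

    @property
    def total_records(self) -> int:
        return sum(self.summary.values())


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def pairwise_similarity(a: str, b: str) -> tuple[float, float]:
    """(percent identity, percent coverage) of the shorter within the longer.

    Infix (semi-global) edit-distance alignment of the shorter sequence
    against the longer, on both strands (elements of one family insert in
    either orientation); identity counts matched columns over alignment
    columns, coverage is the aligned fraction of the shorter sequence
    (100% by construction of the infix alignment).
    """
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    if not query:
        return 0.0, 0.0
    best = 0.0
    for oriented in (query, revcomp(query)):
        res = edlib.align(oriented, target, mode="HW", task="path")
        nice = edlib.getNiceAlignment(res, oriented, target)
        columns = len(nice["matched_aligned"])
        matches = nice["matched_aligned"].count("|")
        if columns:
            best = max(best, 100.0 * matches / columns)
    return best, 100.0


def cluster_families(
    elements: Sequence[ClassifiedTE],
    sequences: Mapping[str, str],
    identity_threshold: float = 70.0,
    coverage_threshold: float = 80.0,
) -> list[TEFamily]:
    """Single-linkage families over the >identity_threshold similarity graph.

    Family ids are assigned by descending member count, then leftmost
    member coordinate; each family's representative is chosen by
    ``pick_representative``.
    """
    if not elements:
        raise ValueError("need at least one element to cluster")
    elems = sorted(elements, key=lambda e: (e.seq_id, e.span, e.element_id))
    ids = [e.element_id for e in elems]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate element ids")
    dsu = _DSU(len(elems))
    for i in range(len(elems)):
        for j in range(i + 1, len(elems)):
            ident, cov = pairwise_similarity(
                sequences[ids[i]], sequences[ids[j]]
            )
            if ident > identity_threshold and cov >= coverage_threshold:
                dsu.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(elems)):
        groups.setdefault(dsu.find(i), []).append(i)

    def group_key(members: list[int]):
        first = min((elems[i].seq_id, elems[i].span) for i in members)
        return (-len(members), first)

    ordered = sorted(groups.values(), key=group_key)
    families: list[TEFamily] = []
    per_prefix: dict[str, int] = {}
    for members in ordered:
        sfs = [elems[i].superfamily for i in members]
        superfamily = sorted(
            ((sfs.count(sf), sf) for sf in set(sfs)),
            key=lambda t: (-t[0], t[1]),
        )[0][1]
        prefix = FAMILY_PREFIX.get(superfamily, "XXX")
        per_prefix[prefix] = per_prefix.get(prefix, 0) + 1
        family = TEFamily(
            family_id=f"{prefix}_{per_prefix[prefix]:03d}",
            superfamily=superfamily,
            member_ids=frozenset(ids[i] for i in members),
        )
        family.representative_id = pick_representative(
            family, {ids[i]: elems[i] for i in members}
        )
        families.append(family)
    return families


def pick_representative(
    family: TEFamily, elements: Mapping[str, ClassifiedTE]
) -> str:
    """Intact (complete) and longest member, falling back to the longest
    fragment; ties break to the lexicographically smallest element id."""
    members = [elements[eid] for eid in family.member_ids]
    if not members:
        raise ValueError("family has no members")
    complete = [e for e in members if e.complete]
    pool = complete or members
    pool.sort(key=lambda e: (-e.length, e.element_id))
    return pool[0].element_id


def build_library(
    families: Sequence[TEFamily],
    elements: Mapping[str, ClassifiedTE],
    sequences: Mapping[str, str],
) -> TELibrary:
    """Representative FASTA records plus the Table-1-style summary."""
    records: list[tuple[str, str]] = []
    summary = {cat: 0 for cat in ALL_CATEGORIES}
    seen: set[str] = set()
    for fam in families:
        rep = fam.representative_id or pick_representative(fam, elements)
        if rep in seen:
            raise ValueError(f"duplicate representative {rep}")
        seen.add(rep)
        sf = fam.superfamily if fam.superfamily in ALL_CATEGORIES else (
            "unclassified"
        )
        summary[sf] += 1
        header = f"{fam.family_id}#{RM_CLASS.get(sf, 'Unknown')}"
        records.append((header, sequences[rep]))
    return TELibrary(records=records, summary=summary)


def summarize_counts(counts: Mapping[str, int]) -> pd.DataFrame:
    """Table-1 layout with computed class subtotals and grand total."""
    get = lambda c: int(counts.get(c, 0))  # noqa: E731
    class1 = sum(get(c) for c in CLASS1_CATEGORIES)
    class2 = sum(get(c) for c in CLASS2_CATEGORIES)
    ltr = sum(get(c) for c in ("Ty1-copia", "Ty3-gypsy",
                               "LTR-unclassified"))
    non_ltr = get("LINE") + get("SINE")
    rows = [
        ("Class 1", class1),
        ("LTR retrotransposons", ltr),
        ("Ty1-copia", get("Ty1-copia")),
        ("Ty3-gypsy", get("Ty3-gypsy")),
        ("Unclassified LTR", get("LTR-unclassified")),
        ("Non-LTR retrotransposon", non_ltr),
        ("LINE", get("LINE")),
        ("SINE", get("SINE")),
        ("Class 2", class2),
        ("CACTA", get("CACTA")),
        ("hAT", get("hAT")),
        ("MULE", get("MULE")),
        ("Helitron", get("Helitron")),
        ("PIF/Harbinger", get("PIF/Harbinger")),
        ("Unclassified", get("unclassified")),
        ("Total", class1 + class2 + get("unclassified")),
    ]
    return pd.DataFrame(rows, columns=["category", "count"])


def library_summary_frame(library: TELibrary) -> pd.DataFrame:
    return summarize_counts(library.summary)


def distribution_profile(
    family: TEFamily,
    elements: Mapping[str, ClassifiedTE],
    genomes: Sequence[GenomeSeq],
    window: int = 100_000,
) -> pd.DataFrame:
    """Member-midpoint counts per non-overlapping window along each sequence.

    Counts sum to the family's member count (for members on known
    sequences); layout is BED-graph-like (seq_id, window start/end, count).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    mids: dict[str, list[int]] = {}
    for eid in family.member_ids:
        e = elements[eid]
        mids.setdefault(e.seq_id, []).append(sum(e.span) // 2)
    for genome in genomes:
        n_bins = max(1, -(-genome.length // window))
        counts = np.zeros(n_bins, dtype=int)
        for mid in mids.get(genome.seq_id, []):
            counts[min(mid // window, n_bins - 1)] += 1
        for b in range(n_bins):
            rows.append(dict(
                seq_id=genome.seq_id,
                start=b * window,
                end=min((b + 1) * window, genome.length),
                count=int(counts[b]),
            ))
    return pd.DataFrame(rows, columns=["seq_id", "start", "end", "count"])
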