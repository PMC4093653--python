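"""ORF annotation of LTR-element internal regions and layout classification.

LTR retroelements normally encode a single polyprotein (here called the
retrotransposase).  Some families carry an extra ORF between the
retrotransposase ORF and the 3' LTR: on the sense strand this resembles a
retroviral envelope gene ("env-like"); on the antisense strand it is the
ORF2 arrangement reported for several Ty3-gypsy families.  ORFs are called
stop-to-stop (ATG-initiated, no splicing) in all six frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .domains import STOP_CODONS
from .ltr import LTRCandidate
from .sequences import revcomp

START_CODON = "ATG"


@dataclass(frozen=True)
class ORF:
    span: tuple[int, int]  # within the scanned region, includes the stop
    strand: str
    frame: int
    length_aa: int

    @property
    def midpoint(self) -> float:
        return sum(self.span) / 2


@dataclass
class ORFAnnotation:
    element_id: str
    te_size: int
    ltr_size: int
    orfs: list[tuple[tuple[int, int], str, int, str]]
    # (span within element, strand, aa length, role in {retrotransposase,
    #  extra})
    layout_class: str  # retrotransposase_only / env_like_sense /
    #                    orf2_antisense / no_coding
    superfamily: str = ""


def _scan_strand(seq: str, min_len_aa: int, strand: str) -> list[ORF]:
    n = len(seq)
    work = seq if strand == "+" else revcomp(seq)
    orfs: list[ORF] = []
    for off in range(3):
        start_codon_pos: int | None = None
        for p in range(off, n - 2, 3):
            codon = work[p : p + 3]
            if codon in STOP_CODONS:
                if start_codon_pos is not None:
                    length_aa = (p - start_codon_pos) // 3
                    if length_aa >= min_len_aa:
                        s, e = start_codon_pos, p + 3
                        if strand == "-":
                            s, e = n - e, n - s
                        orfs.append(ORF((s, e), strand, off + 1, length_aa))
                start_codon_pos = None
            elif codon == START_CODON and start_codon_pos is None:
                start_codon_pos = p
    return orfs


def find_orfs(region: str, min_len_aa: int = 150) -> list[ORF]:
    """All ATG-to-stop ORFs of >= ``min_len_aa`` codons, six frames.

    The reported span includes the stop codon; length in amino acids is
    span/3 - 1.  Within one frame, the earliest ATG after the previous
    stop defines the (longest) ORF, so same-frame overlaps are already
    reduced.  Sorted by start coordinate.
    """
    orfs = _scan_strand(region, min_len_aa, "+")
    orfs += _scan_strand(region, min_len_aa, "-")
    return sorted(orfs, key=lambda o: (o.span, o.strand))


def classify_layout(
    element: LTRCandidate,
    orfs: Sequence[ORF],
    retrotransposase_evidence: Sequence["DomainHit"] = (),  # noqa: F821
    superfamily: str = "",
) -> ORFAnnotation:
    """Classify an element's coding layout from its internal-region ORFs.

    ``orfs`` are in element-local coordinates (0 = element start).
    ORFs overlapping a retrotransposase domain hit take the
    retrotransposase role; their union span (frameshifted elements may
    split the polyprotein over several ORFs) anchors the downstream test.
    An extra ORF whose midpoint lies between the retrotransposase ORF's 3'
    end and the 3' LTR is env-like when sense, ORF2 when antisense.
    """
    es, ee = element.element_span
    te_size = ee - es
    ltr_size = element.left_ltr[1] - element.left_ltr[0]
    for orf in orfs:
        if orf.span[0] < 0 or orf.span[1] > te_size:
            raise ValueError("ORF outside the element")

    # element-local spans of retrotransposase evidence
    rt_spans = []
    rt_strands = []
    for hit in retrotransposase_evidence:
        hs, he = hit.genome_span
        s, e = max(0, hs - es), min(te_size, he - es)
        if s < e:
            rt_spans.append((s, e))
            rt_strands.append(hit.strand)

    def overlaps_rt(orf: ORF) -> bool:
        return any(orf.span[0] < e and s < orf.span[1] for s, e in rt_spans)

    rt_orfs = [o for o in orfs if overlaps_rt(o)]
    if not rt_orfs and orfs and not rt_spans:
        # no domain evidence supplied: presume the longest ORF is the
        # retrotransposase so the layout test still has an anchor
        rt_orfs = [max(orfs, key=lambda o: o.length_aa)]
    extra_orfs = [o for o in orfs if o not in rt_orfs]

    annotated = [
        (o.span, o.strand, o.length_aa,
         "retrotransposase" if o in rt_orfs else "extra")
        for o in sorted(orfs, key=lambda o: o.span)
    ]

    if not rt_orfs:
        return ORFAnnotation(
            element_id=f"{element.seq_id}:{es}-{ee}",
            te_size=te_size, ltr_size=ltr_size, orfs=annotated,
            layout_class="no_coding", superfamily=superfamily,
        )

    # orientation of the element = strand of its retrotransposase; the
    # longest RT-overlapping ORF is the polyprotein (shorter overlapping
    # calls on the other strand are translation shadows)
    rt_strand = max(rt_orfs, key=lambda o: o.length_aa).strand
    rt_union = (min(o.span[0] for o in rt_orfs),
                max(o.span[1] for o in rt_orfs))

    def downstream(o: ORF) -> bool:
        if rt_strand == "+":
            return o.midpoint > rt_union[1]
        return o.midpoint < rt_union[0]

    layout = "retrotransposase_only"
    down = [o for o in extra_orfs if downstream(o)]
    if down:
        # the dominant (longest) extra ORF decides the layout; short
        # overlapping antisense shadows of real ORFs are ignored
        lead = max(down, key=lambda o: o.length_aa)
        layout = ("env_like_sense" if lead.strand == rt_strand
                  else "orf2_antisense")
    return ORFAnnotation(
        element_id=f"{element.seq_id}:{es}-{ee}",
        te_size=te_size, ltr_size=ltr_size, orfs=annotated,
        layout_class=layout, superfamily=superfamily,
    )


def layout_census(
    annotations: Sequence[ORFAnnotation],
    superfamilies: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-superfamily fraction of retrotransposase-only layouts.

    Percentages are printed to one decimal (half-up); empty groups are
    omitted.
    """
    from .est import _pct

    groups: dict[str, list[ORFAnnotation]] = {}
    for ann in annotations:
        sf = ann.superfamily or (superfamilies or {}).get(
            ann.element_id, ""
        )
        if not sf:
            continue
        groups.setdefault(sf, []).append(ann)
    rows = []
    for sf in sorted(groups):
        anns = groups[sf]
        n_only = sum(
            1 for a in anns if a.layout_class == "retrotransposase_only"
        )
        rows.append(dict(
            superfamily=sf, n_families=len(anns),
            retrotransposase_only=n_only,
            pct_retrotransposase_only=_pct(n_only, len(anns)),
        ))
    return pd.DataFrame(
        rows, columns=["superfamily", "n_families",
                       "retrotransposase_only",
                       "pct_retrotransposase_only"],
    )


def annotations_frame(annotations: Sequence[ORFAnnotation]) -> pd.DataFrame:
    """Table-2-style layout: sizes plus retrotransposase / extra ORF sizes."""
    rows = []
    for a in annotations:
        rt = ",".join(
            str(aa) for span, strand, aa, role in a.orfs
            if role == "retrotransposase"
        )
        extra = ",".join(
            str(aa) for span, strand, aa, role in a.orfs if role == "extra"
        )
        rows.append(dict(
            element_id=a.element_id, superfamily=a.superfamily,
            te_size=a.te_size, ltr_size=a.ltr_size,
            retrotransposase_aa=rt or "-", extra_orf_aa=extra or "-",
            layout=a.layout_class,
        ))
    return pd.DataFrame(
        rows, columns=["element_id", "superfamily", "te_size", "ltr_size",
                       "retrotransposase_aa", "extra_orf_aa", "layout"],
    )
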