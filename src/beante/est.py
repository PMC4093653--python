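"""EST classification against the representative transposon library.

Each EST is mapped to the library by seeded nucleotide local alignment
(both strands) and assigned the superfamily of its single best hit below
the E-value cutoff (default 1e-5, as in the study); per-superfamily counts
and one-decimal percentages reproduce the study's expression summary
layout, including the DNA-transposon subtotal.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .align import dna_aligner, evalue, kmer_index
from .families import TELibrary
from .sequences import revcomp

logger = logging.getLogger(__name__)

_SEED_K = 11
DNA_SUPERFAMILIES = ("Helitron", "CACTA", "MULE", "hAT", "PIF/Harbinger")


@dataclass
class ESTAssignment:
    est_id: str
    superfamily: str | None
    library_header: str | None
    bit_score: float
    evalue: float


@dataclass
class ESTSummary:
    total_te_ests: int
    per_superfamily: dict[str, tuple[int, float]]  # count, percent
    dna_te_subtotal: tuple[int, float]


def _header_superfamily(header: str) -> str:
    """Superfamily from a RepeatMasker-style ``family#Class/Superfamily``."""
    if "#" not in header:
        return "unclassified"
    rm = header.split("#", 1)[1]
    mapping = {
        "LTR/Copia": "Ty1-copia", "LTR/Gypsy": "Ty3-gypsy",
        "LTR/Unknown": "LTR-unclassified", "LINE": "LINE", "SINE": "SINE",
        "DNA/CACTA": "CACTA", "DNA/hAT": "hAT", "DNA/MULE": "MULE",
        "DNA/PIF-Harbinger": "PIF/Harbinger", "RC/Helitron": "Helitron",
    }
    return mapping.get(rm, "unclassified")


def map_ests(
    ests: Sequence[tuple[str, str] | tuple[str, str, str]],
    library: TELibrary,
    evalue_cutoff: float = 1e-5,
) -> list[ESTAssignment]:
    """Best-hit-only assignment of each EST to a library superfamily.

    Scoring is +1/-2 with gap open -2 / extend -1; E = m*n*2^(-S) with m
    the total library length and n the EST length.  Ties on bit score go
    to the record earliest in library order (logged).
    """
    if not library.records:
        raise ValueError("library is empty")
    m_total = library.total_bp
    indexes = [
        (header, seq, kmer_index(seq, _SEED_K, max_occurrences=50))
        for header, seq in library.records
    ]
    aligner = dna_aligner()
    out: list[ESTAssignment] = []
    for est in ests:
        est_id, est_seq = est[0], est[1]
        best: tuple[float, int, str] | None = None  # (score, lib_idx, header)
        tie = False
        for orient_seq in (est_seq, revcomp(est_seq)):
            for idx, (header, lib_seq, lib_index) in enumerate(indexes):
                diags = defaultdict(int)
                for j in range(len(orient_seq) - _SEED_K + 1):
                    for p in lib_index.get(
                            orient_seq[j : j + _SEED_K], ()):
                        diags[p - j] += 1
                if not diags:
                    continue
                # align around the densest diagonal band
                diag = max(diags, key=lambda d: (diags[d], -abs(d)))
                lo = max(0, diag - len(orient_seq))
                hi = min(len(lib_seq), diag + 2 * len(orient_seq))
                score = float(aligner.score(lib_seq[lo:hi], orient_seq))
                if best is None or score > best[0]:
                    best = (score, idx, header)
                    tie = False
                elif score == best[0] and idx != best[1]:
                    tie = True
        if best is not None:
            score, _idx, header = best
            ev = evalue(score, m_total, len(est_seq))
            if ev < evalue_cutoff:
                if tie:
                    logger.info(
                        "%s: tied best hits; keeping first library record",
                        est_id,
                    )
                out.append(ESTAssignment(
                    est_id, _header_superfamily(header), header,
                    score, ev,
                ))
                continue
        out.append(ESTAssignment(est_id, None, None, 0.0, float("inf")))
    return out


def counts_from_assignments(
    assignments: Sequence[ESTAssignment],
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a in assignments:
        if a.superfamily is not None:
            counts[a.superfamily] = counts.get(a.superfamily, 0) + 1
    return counts


def _pct(count: int, total: int) -> float:
    """Percent to one decimal, half-up (the printed precision)."""
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def summarize_est_hits(
    counts: Mapping[str, int] | Sequence[ESTAssignment],
    total: int,
) -> ESTSummary:
    """Per-superfamily counts and one-decimal percentages against ``total``.

    ``total`` is the stated number of TE-related ESTs; it need not equal
    the sum of the category counts.  The DNA-transposon subtotal covers
    Helitron, CACTA, MULE, hAT and PIF/Harbinger.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not isinstance(counts, Mapping):
        counts = counts_from_assignments(counts)
    per = {
        sf: (int(n), _pct(int(n), total)) for sf, n in sorted(counts.items())
    }
    dna_count = sum(int(counts.get(sf, 0)) for sf in DNA_SUPERFAMILIES)
    return ESTSummary(
        total_te_ests=total,
        per_superfamily=per,
        dna_te_subtotal=(dna_count, _pct(dna_count, total)),
    )


def summary_frame(summary: ESTSummary) -> pd.DataFrame:
    rows = [
        dict(superfamily=sf, count=n, percent=p)
        for sf, (n, p) in summary.per_superfamily.items()
    ]
    rows.append(dict(superfamily="DNA transposons (subtotal)",
                     count=summary.dna_te_subtotal[0],
                     percent=summary.dna_te_subtotal[1]))
    return pd.DataFrame(rows, columns=["superfamily", "count", "percent"])


def plot_summary(summary: ESTSummary, path) -> None:
    """Stacked-bar style figure of per-superfamily EST counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(summary.per_superfamily)
    values = [summary.per_superfamily[n][0] for n in names]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(names, values, color="#4477aa")
    ax.set_ylabel("TE-related ESTs")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
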