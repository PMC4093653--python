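"""Shared pairwise-alignment and seeding utilities.

All heuristics in the toolkit follow the classic seed-and-extend pattern:
exact k-mer seeds locate candidate regions, then a proper dynamic-programming
alignment (Biopython's PairwiseAligner) scores the bounded region.  E-values
use the simple, conservative bound E = m * n * 2^(-bits) rather than fitted
Karlin-Altschul parameters; with BLOSUM62 (half-bit units) bits = score / 2,
with the nucleotide scheme the raw score is taken as bits.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping

from Bio import Align
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: nucleotide local-alignment scoring used for EST mapping
NT_MATCH, NT_MISMATCH, NT_GAP_OPEN, NT_GAP_EXTEND = 1, -2, -2, -1


def protein_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def dna_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = NT_MATCH
    aligner.mismatch_score = NT_MISMATCH
    aligner.open_gap_score = NT_GAP_OPEN
    aligner.extend_gap_score = NT_GAP_EXTEND
    return aligner


def dna_global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    # end gaps free so that terminal overhangs are not forced into the body
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def alignment_identity(alignment, target: str, query: str) -> tuple[float, int]:
    """Percent identity over aligned columns, excluding terminal gaps.

    Columns counted: identities + mismatches + internal gap columns between
    the first and last aligned pair.  Returns (percent_identity, columns).
    """
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return 0.0, 0
    identities = 0
    aligned = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        aligned += te - ts
        identities += sum(
            1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b
        )
    gap_cols = 0
    for i in range(1, len(t_blocks)):
        gap_cols += t_blocks[i][0] - t_blocks[i - 1][1]
        gap_cols += q_blocks[i][0] - q_blocks[i - 1][1]
    columns = aligned + gap_cols
    return 100.0 * identities / columns, columns


def global_identity(a: str, b: str) -> float:
    """Percent identity of a global DNA alignment of two sequences."""
    if not a or not b:
        return 0.0
    if a == b:
        return 100.0
    aligner = dna_global_aligner()
    alignment = aligner.align(a, b)[0]
    identity, _ = alignment_identity(alignment, a, b)
    return identity


def best_local_score(target: str, query: str, *, protein: bool) -> float:
    """Optimal local alignment score of query within target."""
    if not target or not query:
        return 0.0
    aligner = protein_aligner() if protein else dna_aligner()
    return float(aligner.score(target, query))


def kmer_index(
    seq: str, k: int, *, max_occurrences: int | None = None
) -> Mapping[str, list[int]]:
    """Exact k-mer -> sorted positions; k-mers containing N are skipped.

    ``max_occurrences`` drops hyper-abundant (low-complexity) k-mers.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index[kmer].append(i)
    if max_occurrences is not None:
        index = {
            kmer: pos
            for kmer, pos in index.items()
            if len(pos) <= max_occurrences
        }
    return index


def evalue(bit_score: float, m: int, n: int) -> float:
    """E = m * n * 2^(-bits); conservative fixed-parameter bound."""
    if bit_score > 4000:  # avoid underflow-to-denormal churn
        return 0.0
    return m * n * 2.0 ** (-bit_score)
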