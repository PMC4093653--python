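"""Nucleotide sequence container and FASTA / GFF3 helpers.

``GenomeSeq`` is the universal substrate of the toolkit: a named nucleotide
string over {A,C,G,T,N} with 0-based half-open interval semantics everywhere.
File I/O goes through Biopython; GFF3 export converts to the format's 1-based
closed coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = re.compile(r"^[ACGTN]*$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomeSeq:
    """A named nucleotide sequence (uppercase A/C/G/T/N)."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not _VALID.match(self.residues):
            raise ValueError(
                f"{self.seq_id}: residues contain characters outside A/C/G/T/N"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Substring on the 0-based half-open interval [start, end)."""
        if start < 0 or end > len(self.residues) or start > end:
            raise ValueError(
                f"interval [{start},{end}) outside sequence {self.seq_id} "
                f"of length {len(self.residues)}"
            )
        return self.residues[start:end]

    def reverse_complement(self) -> "GenomeSeq":
        return GenomeSeq(self.seq_id, revcomp(self.residues))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[GenomeSeq]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeSeq(rec.id, str(rec.seq).upper()))
    ids = [r.seq_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sequence ids in {path}")
    return records


def write_fasta(
    records: Iterable[GenomeSeq | SeqRecord | tuple],
    path: str | Path,
    width: int = 60,
) -> None:
    """Write records (GenomeSeq, SeqRecord, or (id, seq[, description]) tuples)."""

    def as_seqrecord(rec) -> SeqRecord:
        if isinstance(rec, SeqRecord):
            return rec
        if isinstance(rec, GenomeSeq):
            return SeqRecord(Seq(rec.residues), id=rec.seq_id, description="")
        rec = tuple(rec)
        desc = rec[2] if len(rec) > 2 else ""
        return SeqRecord(Seq(rec[1]), id=rec[0], description=desc)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(as_seqrecord(r) for r in records)


def gff3_escape(value: str) -> str:
    return (
        str(value)
        .replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def gff3_line(
    seq_id: str,
    source: str,
    feature_type: str,
    start0: int,
    end0: int,
    score: str = ".",
    strand: str = ".",
    attributes: dict | None = None,
) -> str:
    """Render one GFF3 line from 0-based half-open coordinates."""
    attrs = ";".join(
        f"{k}={gff3_escape(v)}" for k, v in (attributes or {}).items()
    ) or "."
    return "\t".join(
        [seq_id, source, feature_type, str(start0 + 1), str(end0), score,
         strand, ".", attrs]
    )


def write_gff3(lines: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in lines:
            fh.write(line + "\n")


def iter_windows(seq: str, size: int) -> Iterator[tuple[int, str]]:
    for i in range(0, len(seq), size):
        yield i, seq[i : i + size]
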