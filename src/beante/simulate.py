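"""Truth-tracked synthetic genome and EST simulator.

Generates small plant-like genomes with planted transposable elements of all
nine supported superfamilies, each carrying the structural hallmarks the
annotation stages look for: target-site duplications (TSDs), TG...CA long
terminal repeats, superfamily terminal motifs / terminal inverted repeats,
polyA tails, and coding regions built around fixed conserved-domain
peptides.  Every planted element is described exactly by a ``TruthRecord``
so recovery can be scored without any external data.

Model notes
-----------
* Background is i.i.d. nucleotides at a configurable GC content (no
  isochores, no repeat shadows).
* Elements are planted non-nested with a minimum spacing; the TSD is a
  literal duplication of the host sequence at the insertion point, written
  on both flanks.
* Divergence is substitutions-only.  Substitutions that would create a stop
  codon inside a planted reading frame are re-drawn (purifying selection on
  the coding regions of young, potentially active elements), and diagnostic
  terminal motif bases are exempt from mutation, so structural recovery
  measures detector behaviour rather than motif erosion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .domains import DOMAIN_PEPTIDES, STOP_CODONS, SYNONYMOUS_CODONS
from .sequences import GenomeSeq, gff3_line, revcomp, write_fasta, write_gff3

SUPERFAMILIES = (
    "Ty1-copia", "Ty3-gypsy", "CACTA", "hAT", "MULE",
    "PIF/Harbinger", "Helitron", "LINE", "SINE",
)

#: TSD length range planted per superfamily (drawn uniformly, inclusive)
TSD_LEN = {
    "Ty1-copia": (4, 6), "Ty3-gypsy": (4, 6),
    "CACTA": (2, 3), "hAT": (8, 8), "MULE": (9, 11),
    "PIF/Harbinger": (3, 3), "Helitron": (0, 0),
    "LINE": (5, 29), "SINE": (5, 15),
}

_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

DEFAULT_COUNTS: dict[str, int] = {
    "Ty1-copia": 6, "Ty3-gypsy": 8, "CACTA": 6, "hAT": 3, "MULE": 3,
    "PIF/Harbinger": 2, "Helitron": 2, "LINE": 4, "SINE": 2,
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome.

    Defaults emulate a compact 1-Mb genome with a handful of multi-member
    families per superfamily; divergences are per-site substitution rates
    relative to the family consensus (members of one family therefore differ
    pairwise by up to roughly twice ``element_divergence``).
    """

    genome_length: int = 1_000_000
    n_elements: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COUNTS)
    )
    gc_content: float = 0.35
    ltr_length: tuple[int, int] = (200, 600)
    ltr_divergence: tuple[float, float] = (0.0, 0.05)
    element_divergence: tuple[float, float] = (0.0, 0.10)
    members_per_family: int = 3
    n_env_like: int = 1  # Ty1-copia families carrying a sense extra ORF
    n_orf2: int = 2      # Ty3-gypsy families carrying an antisense extra ORF
    est_count: int = 500
    est_length: tuple[int, int] = (200, 500)
    est_te_fraction: float = 0.3
    est_error: tuple[float, float] = (0.01, 0.02)
    min_spacing: int = 1000
    cacta_three_prime: str = "ATGTG"  # literal motif; alternative "TAGTG"
    seq_id: str = "chr1"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "est_te_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("ltr_divergence", "element_divergence", "est_error"):
            lo, hi = getattr(self, name)
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError(f"{name} range invalid: ({lo},{hi})")
        unknown = set(self.n_elements) - set(SUPERFAMILIES)
        if unknown:
            raise ValueError(f"unknown superfamilies: {sorted(unknown)}")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one planted element (genome coordinates)."""

    element_id: str
    superfamily: str
    seq_id: str
    span: tuple[int, int]
    strand: str
    tsd: str
    ltr_spans: tuple[tuple[int, int], tuple[int, int]] | None
    orf_layout: list[tuple[tuple[int, int], str, str]]
    family_label: str
    divergence: float

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    def check_against(self, genome: GenomeSeq) -> None:
        """Re-validate every structural invariant against the genome."""
        start, end = self.span
        if not (0 <= start < end <= genome.length):
            raise AssertionError(f"{self.element_id}: span outside genome")
        t = len(self.tsd)
        if t:
            left = genome.slice(start - t, start)
            right = genome.slice(end, end + t)
            if left != self.tsd or right != self.tsd:
                raise AssertionError(f"{self.element_id}: TSD flanks differ")
        for pair in (self.ltr_spans or ()):
            if not (start <= pair[0] < pair[1] <= end):
                raise AssertionError(f"{self.element_id}: LTR outside span")
        for (s, e), _strand, _role in self.orf_layout:
            if not (start <= s < e <= end):
                raise AssertionError(f"{self.element_id}: ORF outside span")


# ---------------------------------------------------------------------------
# element construction (all coordinates element-local, + orientation)

@dataclass
class _ElementTemplate:
    seq: str
    ltr_spans: tuple[tuple[int, int], tuple[int, int]] | None
    orfs: list[tuple[tuple[int, int], str, str]]  # (span, strand, role)
    protected: set[int]

    @property
    def coding_frames(self) -> list[tuple[int, int, str]]:
        return [(s, e, strand) for (s, e), strand, _ in self.orfs]


def _rand_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)
    return arr.tobytes().decode("ascii")


def _orf_nt(rng: np.random.Generator, peptide: str | None,
            filler_codons: int) -> str:
    # domain peptides are encoded with random synonymous codons per family
    # consensus: real TE families conserve their domains at the protein
    # level while drifting apart in DNA, and family clustering must not be
    # able to ride on a verbatim shared DNA block
    body = "".join(
        SYNONYMOUS_CODONS[aa][int(rng.integers(len(SYNONYMOUS_CODONS[aa])))]
        for aa in peptide
    ) if peptide else ""
    filler = "".join(
        _NON_STOP_CODONS[int(i)]
        for i in rng.integers(0, len(_NON_STOP_CODONS), size=filler_codons)
    )
    return "ATG" + body + filler + "TGA"


def _protect_span(protected: set[int], start: int, end: int) -> None:
    protected.update(range(start, end))


def _build_ltr_template(
    rng: np.random.Generator, cfg: SimConfig, superfamily: str,
    extra_role: str | None,
) -> _ElementTemplate:
    ltr_len = int(rng.integers(cfg.ltr_length[0], cfg.ltr_length[1] + 1))
    ltr = "TG" + _rand_nt(rng, ltr_len - 4, cfg.gc_content) + "CA"
    peptide = DOMAIN_PEPTIDES[superfamily]
    parts: list[str] = [ltr]
    orfs: list[tuple[tuple[int, int], str, str]] = []
    pos = ltr_len

    def pad(lo: int, hi: int) -> None:
        nonlocal pos
        chunk = _rand_nt(rng, int(rng.integers(lo, hi)), cfg.gc_content)
        parts.append(chunk)
        pos += len(chunk)

    pad(150, 400)
    rt = _orf_nt(rng, peptide, int(rng.integers(250, 450)))
    orfs.append(((pos, pos + len(rt)), "+", "retrotransposase"))
    parts.append(rt)
    pos += len(rt)
    pad(100, 300)
    if extra_role == "env-like":
        extra = _orf_nt(rng, None, int(rng.integers(220, 340)))
        orfs.append(((pos, pos + len(extra)), "+", "env-like"))
        parts.append(extra)
        pos += len(extra)
        pad(80, 200)
    elif extra_role == "orf2":
        extra = _orf_nt(rng, None, int(rng.integers(220, 340)))
        orfs.append(((pos, pos + len(extra)), "-", "orf2"))
        parts.append(revcomp(extra))
        pos += len(extra)
        pad(80, 200)
    parts.append(ltr)
    seq = "".join(parts)
    total = len(seq)
    protected: set[int] = set()
    # terminal TG / CA dinucleotides of both LTR copies stay diagnostic
    for s, e in ((0, ltr_len), (total - ltr_len, total)):
        _protect_span(protected, s, s + 2)
        _protect_span(protected, e - 2, e)
    for (s, e), strand, _role in orfs:
        if strand == "+":
            _protect_span(protected, s, s + 3)      # ATG
            _protect_span(protected, e - 3, e)      # stop
        else:
            _protect_span(protected, e - 3, e)
            _protect_span(protected, s, s + 3)
    return _ElementTemplate(
        seq, ((0, ltr_len), (total - ltr_len, total)), orfs, protected
    )


def _build_tir_template(
    rng: np.random.Generator, cfg: SimConfig, superfamily: str,
    tir_len: int, five: str = "", three: str = "",
    coding: bool = True,
) -> _ElementTemplate:
    gc = cfg.gc_content
    tir = _rand_nt(rng, tir_len, gc) if tir_len else ""
    left_end = five or tir
    right_end = three or (revcomp(tir) if tir else "")
    parts = [left_end]
    pos = len(left_end)
    orfs: list[tuple[tuple[int, int], str, str]] = []
    pad1 = _rand_nt(rng, int(rng.integers(100, 300)), gc)
    parts.append(pad1)
    pos += len(pad1)
    if coding:
        orf = _orf_nt(rng, DOMAIN_PEPTIDES[superfamily],
                      int(rng.integers(120, 300)))
        orfs.append(((pos, pos + len(orf)), "+", "transposase"))
        parts.append(orf)
        pos += len(orf)
    pad2 = _rand_nt(rng, int(rng.integers(100, 300)), gc)
    parts.append(pad2)
    pos += len(pad2)
    parts.append(right_end)
    seq = "".join(parts)
    protected: set[int] = set()
    _protect_span(protected, 0, min(5, len(left_end)))
    _protect_span(protected, len(seq) - min(5, len(right_end)), len(seq))
    for (s, e), _strand, _role in orfs:
        _protect_span(protected, s, s + 3)
        _protect_span(protected, e - 3, e)
    return _ElementTemplate(seq, None, orfs, protected)


def _build_line_template(
    rng: np.random.Generator, cfg: SimConfig, short: bool = False
) -> _ElementTemplate:
    gc = cfg.gc_content
    if short:  # SINE: short, non-coding, polyA-terminated
        body = _rand_nt(rng, int(rng.integers(120, 400)), gc)
        tail = "A" * int(rng.integers(12, 21))
        seq = body + tail
        protected = set(range(len(body), len(seq)))
        return _ElementTemplate(seq, None, [], protected)
    head = _rand_nt(rng, int(rng.integers(150, 300)), gc)
    orf = _orf_nt(rng, DOMAIN_PEPTIDES["LINE"], int(rng.integers(200, 400)))
    mid = _rand_nt(rng, int(rng.integers(150, 400)), gc)
    tail = "A" * int(rng.integers(15, 36))
    seq = head + orf + mid + tail
    s = len(head)
    orfs = [((s, s + len(orf)), "+", "retrotransposase")]
    protected = set(range(len(seq) - len(tail), len(seq)))
    _protect_span(protected, s, s + 3)
    _protect_span(protected, s + len(orf) - 3, s + len(orf))
    return _ElementTemplate(seq, None, orfs, protected)


def _build_template(
    rng: np.random.Generator, cfg: SimConfig, superfamily: str,
    extra_role: str | None,
) -> _ElementTemplate:
    if superfamily in ("Ty1-copia", "Ty3-gypsy"):
        return _build_ltr_template(rng, cfg, superfamily, extra_role)
    if superfamily == "CACTA":
        return _build_tir_template(
            rng, cfg, superfamily, 0, five="CACTA",
            three=cfg.cacta_three_prime,
        )
    if superfamily == "hAT":
        return _build_tir_template(rng, cfg, superfamily, 15)
    if superfamily == "MULE":
        return _build_tir_template(rng, cfg, superfamily, 60)
    if superfamily == "PIF/Harbinger":
        return _build_tir_template(rng, cfg, superfamily, 14)
    if superfamily == "Helitron":
        return _build_tir_template(rng, cfg, superfamily, 0, coding=True)
    if superfamily == "LINE":
        return _build_line_template(rng, cfg)
    if superfamily == "SINE":
        return _build_line_template(rng, cfg, short=True)
    raise ValueError(f"unknown superfamily {superfamily}")


# ---------------------------------------------------------------------------
# mutation with frame-aware stop avoidance

def _codon_ok(seq: list[str], pos: int, base: str,
              frames: Sequence[tuple[int, int, str]]) -> bool:
    for s, e, strand in frames:
        if not (s <= pos < e):
            continue
        if strand == "+":
            ci = (pos - s) // 3
            cs = s + 3 * ci
            codon = "".join(
                base if p == pos else seq[p] for p in range(cs, cs + 3)
            )
            if codon in STOP_CODONS:
                return False
        else:
            ci = (e - 1 - pos) // 3
            cs = e - 3 * (ci + 1)
            fwd = "".join(
                base if p == pos else seq[p] for p in range(cs, cs + 3)
            )
            if revcomp(fwd) in STOP_CODONS:
                return False
    return True


def _mutate(
    seq: str, rate: float, rng: np.random.Generator,
    frames: Sequence[tuple[int, int, str]] = (),
    protected: set[int] | frozenset[int] = frozenset(),
    span: tuple[int, int] | None = None,
) -> str:
    """Apply i.i.d. substitutions at ``rate`` within ``span`` (default: all).

    Protected positions are skipped; substitutions creating an in-frame stop
    codon are re-drawn among the remaining bases or skipped.
    """
    lo, hi = span if span else (0, len(seq))
    n = hi - lo
    if n <= 0 or rate <= 0:
        return seq
    n_sub = rng.binomial(n, rate)
    if n_sub == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(n, size=n_sub, replace=False) + lo
    for pos in sorted(int(p) for p in positions):
        if pos in protected:
            continue
        old = chars[pos]
        options = [b for b in "ACGT" if b != old]
        order = rng.permutation(len(options))
        for idx in order:
            base = options[int(idx)]
            if _codon_ok(chars, pos, base, frames):
                chars[pos] = base
                break
    return "".join(chars)


# ---------------------------------------------------------------------------
# genome assembly

def _flip_template(tpl: _ElementTemplate) -> _ElementTemplate:
    """Reverse-complement a template, mirroring all local coordinates."""
    n = len(tpl.seq)
    flip = lambda span: (n - span[1], n - span[0])  # noqa: E731
    ltr = None
    if tpl.ltr_spans:
        a, b = tpl.ltr_spans
        ltr = (flip(b), flip(a))
    orfs = [
        (flip(span), "-" if strand == "+" else "+", role)
        for span, strand, role in tpl.orfs
    ]
    protected = {n - 1 - p for p in tpl.protected}
    return _ElementTemplate(revcomp(tpl.seq), ltr, orfs, protected)


def simulate_genome(
    config: SimConfig,
) -> tuple[list[GenomeSeq], list[TruthRecord]]:
    """Build one genome and the exact truth list for every planted element.

    Raises ``ValueError`` ("genome too small") when the requested elements
    plus minimum spacing exceed ``genome_length``.
    """
    rng = np.random.default_rng(config.rng_seed)
    # family consensus templates
    instances: list[tuple[str, str, _ElementTemplate, float]] = []
    for sf in SUPERFAMILIES:
        count = int(config.n_elements.get(sf, 0))
        if count <= 0:
            continue
        n_fam = math.ceil(count / max(1, config.members_per_family))
        roles: list[str | None] = [None] * n_fam
        if sf == "Ty1-copia":
            for i in range(min(config.n_env_like, n_fam)):
                roles[i] = "env-like"
        if sf == "Ty3-gypsy":
            for i in range(min(config.n_orf2, n_fam)):
                roles[i] = "orf2"
        templates = [
            (f"{sf}.F{i + 1:02d}", _build_template(rng, config, sf, roles[i]))
            for i in range(n_fam)
        ]
        for j in range(count):
            label, tpl = templates[j % n_fam]
            div = float(rng.uniform(*config.element_divergence))
            instances.append((sf, label, tpl, div))

    # instantiate each element from its family consensus
    planted: list[dict] = []
    for sf, label, tpl, div in instances:
        seq = _mutate(tpl.seq, div, rng, frames=tpl.coding_frames,
                      protected=tpl.protected)
        ltr_spans = tpl.ltr_spans
        if ltr_spans is not None:
            (ls, le), (rs, re_) = ltr_spans
            ltr_div = float(rng.uniform(*config.ltr_divergence))
            chars = list(seq)
            chars[rs:re_] = chars[ls:le]  # right LTR starts identical to left
            seq = "".join(chars)
            seq = _mutate(seq, ltr_div, rng, protected=tpl.protected,
                          span=(rs, re_))
        inst = _ElementTemplate(seq, ltr_spans, list(tpl.orfs),
                                set(tpl.protected))
        if rng.random() < 0.5:
            inst = _flip_template(inst)
            strand = "-"
        else:
            strand = "+"
        tsd_lo, tsd_hi = TSD_LEN[sf]
        tsd_len = int(rng.integers(tsd_lo, tsd_hi + 1)) if tsd_hi else 0
        planted.append(dict(superfamily=sf, family=label, template=inst,
                            strand=strand, tsd_len=tsd_len, divergence=div))

    rng.shuffle(planted)

    total_planted = sum(
        len(p["template"].seq) + p["tsd_len"] for p in planted
    )
    bg_len = config.genome_length - total_planted
    n = len(planted)
    min_bg = (n + 1) * config.min_spacing
    if bg_len < min_bg:
        raise ValueError(
            f"genome too small: need >= {total_planted + min_bg} bp for "
            f"{n} elements with {config.min_spacing} bp spacing, "
            f"got {config.genome_length}"
        )
    background = _rand_nt(rng, bg_len, config.gc_content)
    extra = bg_len - min_bg
    gap_extra = rng.multinomial(extra, [1.0 / (n + 1)] * (n + 1)) if n else [
        extra
    ]
    gaps = [config.min_spacing + int(g) for g in gap_extra]

    pieces: list[str] = []
    truth: list[TruthRecord] = []
    bg_pos = 0
    out_pos = 0
    for i, p in enumerate(planted):
        gap = gaps[i]
        pieces.append(background[bg_pos : bg_pos + gap])
        bg_pos += gap
        out_pos += gap
        t = p["tsd_len"]
        tsd = background[bg_pos - t : bg_pos] if t else ""
        tpl: _ElementTemplate = p["template"]
        start = out_pos
        pieces.append(tpl.seq)
        out_pos += len(tpl.seq)
        end = out_pos
        if t:
            pieces.append(tsd)
            out_pos += t
        ltr_spans = None
        if tpl.ltr_spans:
            ltr_spans = tuple(
                (start + a, start + b) for a, b in tpl.ltr_spans
            )
        orf_layout = [
            ((start + s, start + e), strand, role)
            for (s, e), strand, role in tpl.orfs
        ]
        truth.append(TruthRecord(
            element_id=f"TE{i + 1:04d}",
            superfamily=p["superfamily"],
            seq_id=config.seq_id,
            span=(start, end),
            strand=p["strand"],
            tsd=tsd,
            ltr_spans=ltr_spans,  # type: ignore[arg-type]
            orf_layout=orf_layout,
            family_label=p["family"],
            divergence=p["divergence"],
        ))
    pieces.append(background[bg_pos:])
    genome = GenomeSeq(config.seq_id, "".join(pieces))
    assert genome.length == config.genome_length
    for rec in truth:
        rec.check_against(genome)
    return [genome], truth


# ---------------------------------------------------------------------------
# EST simulation

def simulate_ests(
    config: SimConfig,
    genomes: Sequence[GenomeSeq],
    truth: Sequence[TruthRecord],
) -> list[tuple[str, str, str]]:
    """Sample an EST pool as (id, sequence, description) tuples.

    A fraction ``est_te_fraction`` of reads come from planted element bodies
    (with 1-2% substitution error by default); the rest come from the non-TE
    background.  The description labels the true source for truth checking.
    """
    rng = np.random.default_rng((config.rng_seed, 7919))
    genome = genomes[0]
    lo, hi = config.est_length
    if lo > genome.length:
        raise ValueError("est_length exceeds genome length")
    spans = sorted(rec.span for rec in truth)

    def overlaps_te(s: int, e: int) -> bool:
        for ts, te in spans:
            if s < te and ts < e:
                return True
        return False

    reads: list[tuple[str, str, str]] = []
    for i in range(config.est_count):
        length = int(rng.integers(lo, hi + 1))
        is_te = bool(truth) and rng.random() < config.est_te_fraction
        if is_te:
            rec = truth[int(rng.integers(len(truth)))]
            span_len = rec.length
            rlen = min(length, span_len)
            off = int(rng.integers(0, span_len - rlen + 1))
            s = rec.span[0] + off
            seq = genome.slice(s, s + rlen)
            source, sf = rec.element_id, rec.superfamily
        else:
            while True:
                rlen = min(length, genome.length)
                s = int(rng.integers(0, genome.length - rlen + 1))
                if not overlaps_te(s, s + rlen):
                    break
            seq = genome.slice(s, s + rlen)
            source, sf = "background", "NA"
        err = float(rng.uniform(*config.est_error))
        seq = _mutate(seq, err, rng)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(
            (f"EST{i + 1:06d}", seq, f"src={source} superfamily={sf}")
        )
    return reads


# ---------------------------------------------------------------------------
# serialization

def truth_to_gff3(truth: Sequence[TruthRecord], path: str | Path) -> None:
    lines = []
    for rec in truth:
        attrs = {
            "ID": rec.element_id,
            "superfamily": rec.superfamily,
            "family": rec.family_label,
            "TSD": rec.tsd or "-",
        }
        if rec.ltr_spans:
            attrs["ltr_spans"] = " ".join(
                f"{a}-{b}" for a, b in rec.ltr_spans
            )
        lines.append(gff3_line(
            rec.seq_id, "beante-sim", "transposable_element",
            rec.span[0], rec.span[1], strand=rec.strand, attributes=attrs,
        ))
    write_gff3(lines, path)


def truth_to_tsv(truth: Sequence[TruthRecord], path: str | Path) -> None:
    import pandas as pd

    rows = [
        dict(element_id=r.element_id, superfamily=r.superfamily,
             seq_id=r.seq_id, start=r.span[0], end=r.span[1],
             strand=r.strand, tsd=r.tsd, family=r.family_label,
             divergence=round(r.divergence, 5))
        for r in truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_simulation(
    config: SimConfig, out_dir: str | Path
) -> tuple[list[GenomeSeq], list[TruthRecord], list[tuple[str, str, str]]]:
    """Run the simulator and write genome/truth/EST files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, truth = simulate_genome(config)
    ests = simulate_ests(config, genomes, truth)
    write_fasta(genomes, out / "genome.fa")
    truth_to_gff3(truth, out / "truth.gff3")
    truth_to_tsv(truth, out / "truth.tsv")
    write_fasta(ests, out / "ests.fa")
    return genomes, truth, ests
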