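"""ORF calling and extra-ORF layout classification."""

import pytest


from beante.homology import DomainHit
from beante.ltr import LTRCandidate
from beante.orfs import ORF, classify_layout, find_orfs, layout_census
from beante.sequences import revcomp

from conftest import random_dna
from oracles import codon_walk_orfs


def _orf_nt(rng, n_aa):
    """ATG + (n_aa - 1) random sense codons + stop: an n_aa-aa ORF.

    Codons are drawn from all 61 non-stop codons so the antisense read of
    the ORF is interrupted by stops, as in natural coding sequence.
    """
    from beante.simulate import _NON_STOP_CODONS

    body = "".join(
        _NON_STOP_CODONS[int(i)]
        for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_aa - 1)
    )
    return "ATG" + body + "TGA"


class TestFindOrfs:
    def test_stop_saturated_region_has_no_orfs(self):
        assert find_orfs("TAATAGTGA" * 200, 150) == []

    def test_minus_strand_orf_reported_with_length(self, rng):
        orf = _orf_nt(rng, 400)
        region = random_dna(rng, 600) + revcomp(orf) + random_dna(rng, 600)
        found = [o for o in find_orfs(region, 150) if o.strand == "-"]
        assert any(o.length_aa >= 400 for o in found)
        o = max(found, key=lambda o: o.length_aa)
        # the stop codon end is exact; the ATG end may extend through
        # chance upstream in-frame starts (earliest-ATG rule)
        assert o.span[0] == 600
        assert o.span[1] >= 600 + len(orf)

    def test_threshold_excludes_149_codon_orf(self, rng):
        orf = _orf_nt(rng, 149)
        region = "TAA" + orf + "TAA"
        lengths = [o.length_aa for o in find_orfs(region, 150)]
        assert 149 not in lengths
        assert [o.length_aa for o in find_orfs(region, 149)].count(149) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_codon_walk_oracle(self, seed):
        import numpy as np

        r = np.random.default_rng(seed)
        region = random_dna(r, 10_000, gc=0.5)
        got = {(o.span[0], o.span[1], o.strand)
               for o in find_orfs(region, 50)}
        assert got == codon_walk_orfs(region, 50)


def _element(rng, extra=None, rt_strand="+"):
    """Build an element + ORF list + RT hit for layout classification."""
    ltr = "TG" + random_dna(rng, 200) + "CA"
    rt = _orf_nt(rng, 500)
    pieces = [ltr, random_dna(rng, 150),
              rt if rt_strand == "+" else revcomp(rt)]
    rt_start = len(ltr) + 150
    extra_span = None
    if extra is not None:
        gap = random_dna(rng, 100)
        x = _orf_nt(rng, 300)
        pieces += [gap, x if extra == "+" else revcomp(x)]
        extra_span = (rt_start + len(rt) + 100,
                      rt_start + len(rt) + 100 + len(x))
    pieces += [random_dna(rng, 150), ltr]
    seq = "".join(pieces)
    cand = LTRCandidate("chr1", (1000, 1000 + len(seq)),
                        (1000, 1000 + len(ltr)),
                        (1000 + len(seq) - len(ltr), 1000 + len(seq)),
                        100.0, tsd="ACGTA", status="accepted")
    orfs = find_orfs(seq[len(ltr) : len(seq) - len(ltr)], 150)
    orfs = [ORF((o.span[0] + len(ltr), o.span[1] + len(ltr)), o.strand,
                o.frame, o.length_aa) for o in orfs]
    hit = DomainHit("chr1", (1000 + rt_start + 30, 1000 + rt_start + 330),
                    1, rt_strand, 300.0, 1e-40, "q", (0, 0))
    return cand, orfs, [hit]


class TestClassifyLayout:
    def test_single_orf_is_retrotransposase_only(self, rng):
        cand, orfs, hits = _element(rng)
        ann = classify_layout(cand, orfs, hits)
        assert ann.layout_class == "retrotransposase_only"

    def test_sense_extra_orf_downstream_is_env_like(self, rng):
        cand, orfs, hits = _element(rng, extra="+")
        ann = classify_layout(cand, orfs, hits)
        assert ann.layout_class == "env_like_sense"

    def test_antisense_extra_orf_is_orf2(self, rng):
        cand, orfs, hits = _element(rng, extra="-")
        ann = classify_layout(cand, orfs, hits)
        assert ann.layout_class == "orf2_antisense"

    def test_minus_strand_element_classifies_identically(self, rng):
        """Layout is invariant under reverse complement of the element."""
        cand, orfs, hits = _element(rng, extra="-", rt_strand="+")
        fwd = classify_layout(cand, orfs, hits)
        # mirror everything by hand
        n = cand.element_span[1] - cand.element_span[0]
        s0 = cand.element_span[0]
        flip = lambda sp: (s0 + n - (sp[1] - s0),  # noqa: E731
                           s0 + n - (sp[0] - s0))
        cand_rc = LTRCandidate(
            "chr1", cand.element_span, flip(cand.right_ltr),
            flip(cand.left_ltr), 100.0, tsd="ACGTA", status="accepted")
        orfs_rc = [
            ORF((n - o.span[1], n - o.span[0]),
                "-" if o.strand == "+" else "+", o.frame, o.length_aa)
            for o in orfs
        ]
        hits_rc = [DomainHit("chr1", flip(h.genome_span), -1, "-",
                             h.bit_score, h.evalue, h.query_id, (0, 0))
                   for h in hits]
        rc = classify_layout(cand_rc, orfs_rc, hits_rc)
        assert rc.layout_class == fwd.layout_class == "orf2_antisense"

    def test_no_orf_and_no_evidence_is_no_coding(self, rng):
        cand, _orfs, _hits = _element(rng)
        ann = classify_layout(cand, [], [])
        assert ann.layout_class == "no_coding"

    def test_orf_outside_element_is_contract_violation(self, rng):
        cand, orfs, hits = _element(rng)
        bad = [ORF((0, 10_000_000), "+", 1, 100)]
        with pytest.raises(ValueError):
            classify_layout(cand, bad, hits)


class TestCensus:
    def test_fractions_printed_to_one_decimal(self):
        from beante.orfs import ORFAnnotation

        def ann(sf, layout):
            return ORFAnnotation("x", 10_000, 500, [], layout, sf)

        annotations = (
            [ann("Ty1-copia", "retrotransposase_only")] * 63
            + [ann("Ty1-copia", "env_like_sense")] * 2
            + [ann("Ty3-gypsy", "retrotransposase_only")] * 63
            + [ann("Ty3-gypsy", "orf2_antisense")] * 15
            + [ann("SINE", "no_coding")] * 5
        )
        frame = layout_census(annotations).set_index("superfamily")
        assert frame.loc["Ty1-copia", "pct_retrotransposase_only"] == 96.9
        assert frame.loc["Ty3-gypsy", "pct_retrotransposase_only"] == 80.8
        assert frame.loc["SINE", "pct_retrotransposase_only"] == 0.0

    def test_empty_groups_omitted(self):
        assert layout_census([]).empty
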