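"""Structural classifier: TSD finding, superfamily rules, MITE scan."""

import pytest
from hypothesis import given, settings, strategies as st

from beante.classify import (classify_candidate, find_mite_like,
                             find_tsd, locate_element)
from beante.homology import (default_queries, query_superfamily_map,
                             translated_search)
from beante.sequences import GenomeSeq, revcomp
from beante.simulate import SimConfig, simulate_genome

from conftest import random_dna
from oracles import brute_tsd


class TestFindTsd:
    def test_worked_example(self):
        assert find_tsd("TACGATAGC", "TAGCGGTAC", (4, 6)) == "TAGC"

    def test_long_line_style_duplication(self):
        tsd = "ACGTAGGTCCATTTGAACGGATCCTAGGA"  # 29-mer
        left = "GGTT" + tsd
        right = tsd + "CCAA"
        assert find_tsd(left, right, (5, 29)) == tsd

    def test_unrelated_flanks_give_empty(self, rng):
        left, right = random_dna(rng, 30), random_dna(rng, 30)
        # brute-force agreement even when a chance duplication exists
        assert find_tsd(left, right, (4, 6)) == brute_tsd(left, right, 4, 6)

    def test_window_shorter_than_range_raises(self):
        with pytest.raises(ValueError):
            find_tsd("ACG", "ACG", (4, 6))

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=40),
           st.text(alphabet="ACGT", min_size=12, max_size=40))
    def test_matches_brute_force_enumeration(self, left, right):
        assert find_tsd(left, right, (2, 12)) == \
            brute_tsd(left, right, 2, 12)


def _single_element_genome(superfamily, seed, **kwargs):
    cfg = SimConfig(genome_length=60_000,
                    n_elements={superfamily: 1}, rng_seed=seed, **kwargs)
    genomes, truth = simulate_genome(cfg)
    return genomes[0], truth[0]


class TestClassifyCandidate:
    def test_planted_cacta_complete_with_motif_and_tsd(self):
        genome, rec = _single_element_genome("CACTA", 21)
        out = classify_candidate(genome, rec.span)
        assert out.superfamily == "CACTA"
        assert out.evidence >= {"terminal_motif", "tsd"}
        assert out.complete
        assert out.span == rec.span
        assert out.tsd == rec.tsd

    def test_region_may_be_offset_up_to_slide_limit(self):
        genome, rec = _single_element_genome("MULE", 22)
        region = (rec.span[0] + 40, rec.span[1] - 40)
        out = classify_candidate(genome, region)
        assert out.superfamily == "MULE"
        assert out.span == rec.span

    def test_planted_line_with_polya_and_domain_hit(self):
        genome, rec = _single_element_genome("LINE", 23)
        hits = translated_search(genome, default_queries(), 1e-20)
        out = classify_candidate(
            genome, rec.span, hits,
            query_superfamilies=query_superfamily_map(default_queries()),
        )
        assert out.superfamily == "LINE"
        assert "polyA" in out.evidence
        assert "domain_homology" in out.evidence
        assert out.te_class == 1

    def test_featureless_region_is_unclassified(self, random_genome):
        out = classify_candidate(random_genome, (2000, 3500))
        assert out.superfamily == "unclassified"
        assert "terminal_motif" not in out.evidence
        assert "domain_homology" not in out.evidence
        assert not out.complete

    def test_region_outside_genome_raises(self, random_genome):
        with pytest.raises(ValueError):
            classify_candidate(random_genome, (9000, 12_000))

    def test_cacta_never_called_hat_or_mule(self):
        for seed in range(30, 36):
            genome, rec = _single_element_genome("CACTA", seed)
            out = classify_candidate(genome, rec.span)
            assert out.superfamily not in ("hAT", "MULE")

    def test_strand_symmetry_on_reverse_complement(self):
        genome, rec = _single_element_genome("CACTA", 24)
        out_fwd = classify_candidate(genome, rec.span)
        rc = genome.reverse_complement()
        n = genome.length
        region_rc = (n - rec.span[1], n - rec.span[0])
        out_rc = classify_candidate(rc, region_rc)
        assert out_rc.superfamily == out_fwd.superfamily
        assert out_rc.span == (n - out_fwd.span[1], n - out_fwd.span[0])
        assert {out_fwd.strand, out_rc.strand} == {"+", "-"}

    def test_tsd_idempotent_on_complete_elements(self):
        genome, rec = _single_element_genome("hAT", 25)
        out = classify_candidate(genome, rec.span)
        assert out.complete
        s, e = out.span
        w = 20
        again = find_tsd(genome.slice(s - w, s), genome.slice(e, e + w),
                         (len(out.tsd), len(out.tsd)))
        assert again == out.tsd


class TestLocateElement:
    @pytest.mark.parametrize("superfamily", ["CACTA", "hAT", "MULE", "LINE"])
    def test_boundaries_recovered_from_internal_hit(self, superfamily):
        genome, rec = _single_element_genome(superfamily, 26)
        hits = translated_search(genome, default_queries(), 1e-20)
        assert hits
        qmap = query_superfamily_map(default_queries())
        out = locate_element(genome, hits[0], qmap)
        assert out.superfamily == superfamily
        assert out.complete
        # boundaries are exact up to TSD-length ambiguity: when the host
        # duplication happens to extend into the element (or vice versa)
        # the longer parse is locally indistinguishable from the truth
        slack = abs(len(out.tsd) - len(rec.tsd))
        assert abs(out.span[0] - rec.span[0]) <= 3 + slack
        assert abs(out.span[1] - rec.span[1]) <= 3 + slack


class TestFindMiteLike:
    def test_planted_mite_recovered_exactly(self, rng):
        tir = random_dna(rng, 30)
        body = random_dna(rng, 340)
        tsd = "GCATTCGA"  # 8 bp, hAT-style
        element = tir + body + revcomp(tir)
        bg = random_dna(rng, 12_000)
        seq = bg[:5000] + tsd + element + tsd + bg[5000:]
        start = 5000 + len(tsd)
        spans = find_mite_like(GenomeSeq("g", seq))
        assert (start, start + len(element)) in spans

    def test_palindromic_tandem_without_tsd_excluded(self, rng):
        half = random_dna(rng, 60)
        palindrome = half + revcomp(half)
        seq = random_dna(rng, 4000) + palindrome * 3 + random_dna(rng, 4000)
        spans = find_mite_like(GenomeSeq("g", seq))
        for s, e in spans:
            # any report must carry a genuine flanking duplication
            assert seq[s - 3 : s] == seq[e : e + 3] or \
                seq[s - 8 : s] == seq[e : e + 8]

    def test_empty_genome_yields_nothing(self):
        assert find_mite_like(GenomeSeq("g", "ACGT" * 30)) == []
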