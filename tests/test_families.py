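"""Family clustering, representative choice, library summary, distribution."""

import numpy as np
import pytest

from beante.classify import ClassifiedTE
from beante.families import (TEFamily, build_library, cluster_families,
                             distribution_profile, library_summary_frame,
                             pairwise_similarity, pick_representative,
                             summarize_counts)
from beante.sequences import GenomeSeq

from conftest import random_dna
from oracles import connected_components


def _element(eid, length=2000, superfamily="Ty1-copia", complete=True,
             start=0, seq_id="chr1"):
    return ClassifiedTE(
        element_id=eid, seq_id=seq_id, span=(start, start + length),
        strand="+", te_class=1, superfamily=superfamily, tsd="ACGT",
        evidence={"tsd"}, complete=complete,
    )


def _mutate(seq, rate, rng):
    chars = list(seq)
    for i in rng.choice(len(chars), int(rate * len(chars)), replace=False):
        chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
    return "".join(chars)


class TestClusterFamilies:
    def test_single_element_family(self, rng):
        e = _element("E1")
        fams = cluster_families([e], {"E1": random_dna(rng, 2000)})
        assert len(fams) == 1
        assert fams[0].member_ids == {"E1"}
        assert fams[0].representative_id == "E1"

    def test_single_linkage_chaining(self, rng):
        """A-B and B-C similar, A-C below threshold: one chained family."""
        b = random_dna(rng, 2000)
        a = _mutate(b, 0.20, rng)
        c = _mutate(b, 0.20, rng)
        seqs = {"A": a, "B": b, "C": c}
        ab = pairwise_similarity(a, b)[0]
        bc = pairwise_similarity(b, c)[0]
        ac = pairwise_similarity(a, c)[0]
        assert ab > 70 and bc > 70 and ac < 70
        elements = [_element(x, start=i * 3000) for i, x in
                    enumerate("ABC")]
        fams = cluster_families(elements, seqs)
        # oracle: connected components over the explicit >70% edge list
        edges = [p for p, sim in (("AB", ab), ("BC", bc), ("AC", ac))
                 if sim > 70]
        comps = connected_components("ABC", edges)
        assert len(fams) == len(comps) == 1
        assert fams[0].member_ids == {"A", "B", "C"}

    def test_dissimilar_elements_stay_separate(self, rng):
        seqs = {"A": random_dna(rng, 2000), "B": random_dna(rng, 2000)}
        elements = [_element("A"), _element("B", start=5000)]
        fams = cluster_families(elements, seqs)
        assert len(fams) == 2

    def test_partition_invariant_under_input_order(self, rng):
        base = random_dna(rng, 1500)
        seqs = {
            "A": _mutate(base, 0.05, rng), "B": _mutate(base, 0.05, rng),
            "C": random_dna(rng, 1500), "D": random_dna(rng, 1500),
        }
        elements = [_element(x, start=i * 2000)
                    for i, x in enumerate("ABCD")]
        fams1 = cluster_families(elements, seqs)
        fams2 = cluster_families(elements[::-1], seqs)
        as_sets = lambda fams: {f.member_ids for f in fams}  # noqa: E731
        assert as_sets(fams1) == as_sets(fams2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_families([], {})


class TestPickRepresentative:
    def test_complete_beats_longer_fragment(self):
        e1 = _element("short_complete", 5000, complete=True)
        e2 = _element("long_fragment", 9000, complete=False, start=20_000)
        fam = TEFamily("F1", "Ty1-copia",
                       frozenset({"short_complete", "long_fragment"}))
        rep = pick_representative(
            fam, {"short_complete": e1, "long_fragment": e2})
        assert rep == "short_complete"

    def test_all_fragments_longest_wins(self):
        e1 = _element("f3k", 3000, complete=False)
        e2 = _element("f4k", 4000, complete=False, start=10_000)
        fam = TEFamily("F1", "Ty1-copia", frozenset({"f3k", "f4k"}))
        assert pick_representative(fam, {"f3k": e1, "f4k": e2}) == "f4k"

    def test_tie_breaks_to_smaller_id(self):
        e1 = _element("aaa", 3000)
        e2 = _element("bbb", 3000, start=10_000)
        fam = TEFamily("F1", "Ty1-copia", frozenset({"aaa", "bbb"}))
        assert pick_representative(fam, {"aaa": e1, "bbb": e2}) == "aaa"

    def test_adding_shorter_incomplete_member_keeps_representative(self):
        e1 = _element("rep", 5000, complete=True)
        e2 = _element("frag", 2000, complete=False, start=10_000)
        fam_small = TEFamily("F1", "Ty1-copia", frozenset({"rep"}))
        fam_big = TEFamily("F1", "Ty1-copia", frozenset({"rep", "frag"}))
        elems = {"rep": e1, "frag": e2}
        assert pick_representative(fam_small, elems) == \
            pick_representative(fam_big, elems) == "rep"


class TestLibrary:
    def test_summary_totals_are_computed(self, rng):
        seqs = {}
        elements = {}
        fams = []
        for i, sf in enumerate(["Ty1-copia", "Ty3-gypsy", "CACTA"]):
            eid = f"E{i}"
            elements[eid] = _element(eid, superfamily=sf, start=i * 5000)
            seqs[eid] = random_dna(rng, 2000)
            fams.append(TEFamily(f"F{i}", sf, frozenset({eid}), eid))
        lib = build_library(fams, elements, seqs)
        assert lib.total_records == 3
        assert lib.total_bp == 6000
        frame = library_summary_frame(lib)
        assert int(frame.loc[frame.category == "Total", "count"].iloc[0]) == 3
        assert int(frame.loc[frame.category == "Class 1", "count"].iloc[0]) == 2

    def test_duplicate_representative_rejected(self, rng):
        e = _element("E0")
        seqs = {"E0": random_dna(rng, 1000)}
        fams = [TEFamily("F1", "Ty1-copia", frozenset({"E0"}), "E0"),
                TEFamily("F2", "Ty1-copia", frozenset({"E0"}), "E0")]
        with pytest.raises(ValueError, match="duplicate"):
            build_library(fams, {"E0": e}, seqs)

    def test_empty_summary_totals_zero(self):
        frame = summarize_counts({})
        assert int(frame.loc[frame.category == "Total", "count"].iloc[0]) == 0


class TestDistribution:
    def _family(self, positions, seq_id="chr1"):
        elements = {
            f"E{i}": _element(f"E{i}", 1000, start=p, seq_id=seq_id)
            for i, p in enumerate(positions)
        }
        fam = TEFamily("F1", "Ty1-copia", frozenset(elements), "E0")
        return fam, elements

    def test_absent_family_counts_all_zero(self):
        fam, elements = self._family([1000, 2000], seq_id="chr2")
        genome = GenomeSeq("chr1", "A" * 500_000)
        prof = distribution_profile(fam, elements, [genome], 100_000)
        assert prof["count"].sum() == 0

    def test_counts_sum_to_member_count(self, rng):
        positions = list(np.random.default_rng(0).integers(
            0, 490_000, size=10))
        fam, elements = self._family(positions)
        genome = GenomeSeq("chr1", "A" * 500_000)
        prof = distribution_profile(fam, elements, [genome], 50_000)
        assert prof["count"].sum() == 10

    def test_window_larger_than_chromosome_single_bin(self):
        fam, elements = self._family([100, 5000])
        genome = GenomeSeq("chr1", "A" * 10_000)
        prof = distribution_profile(fam, elements, [genome], 100_000)
        assert len(prof) == 1
        assert prof["count"].iloc[0] == 2

    def test_window_must_be_positive(self):
        fam, elements = self._family([100])
        with pytest.raises(ValueError):
            distribution_profile(fam, elements,
                                 [GenomeSeq("chr1", "ACGT")], 0)
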