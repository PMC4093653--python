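"""RT-domain distances, neighbor joining, clade reports."""

import dendropy
import numpy as np
import pytest

from beante.phylo import (DistMatrix, clade_report, neighbor_joining,
                          read_newick, rt_distances, tree_path_distances,
                          write_newick)

from oracles import four_point_topology


def _random_peptide(rng, n=80):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestDistances:
    def test_identical_peptides_have_zero_distance(self, rng):
        p = _random_peptide(rng)
        d = rt_distances([("a", p), ("b", p)])
        assert d.values[0, 1] == 0.0
        assert np.all(np.diag(d.values) == 0)

    def test_ten_of_hundred_substitutions_give_p_distance_point_one(self, rng):
        a = _random_peptide(rng, 100)
        b = list(a)
        for i in range(0, 100, 10):  # ten substitutions, no gaps
            b[i] = "W" if a[i] != "W" else "Y"
        d = rt_distances([("a", a), ("b", "".join(b))])
        assert d.values[0, 1] == pytest.approx(0.10, abs=1e-9)

    def test_illegal_residues_rejected(self, rng):
        with pytest.raises(ValueError):
            rt_distances([("a", "J" * 60), ("b", _random_peptide(rng))])

    def test_short_peptides_rejected(self, rng):
        with pytest.raises(ValueError):
            rt_distances([("a", "ACDE"), ("b", _random_peptide(rng))])


def _additive_matrix_from_tree(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.distance(taxa[labels[i]],
                                                   taxa[labels[j]])
    return DistMatrix(labels, vals)


def _random_tree(rng, n):
    import random

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=n, rng=random.Random(int(rng.integers(1e6))),
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    return tree


class TestNeighborJoining:
    def test_four_taxon_additive_topology_recovered(self):
        # additive matrix for ((A,B),(C,D)) with internal branch 3
        labels = ["A", "B", "C", "D"]
        d = {"A": {"B": 3, "C": 9, "D": 10},
             "B": {"C": 10, "D": 11}, "C": {"D": 3}}
        vals = np.zeros((4, 4))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    v = d[x][y] if y in d.get(x, {}) else d[y][x]
                    vals[i, j] = vals[j, i] = v
        full = {x: {y: vals[i, j] for j, y in enumerate(labels)}
                for i, x in enumerate(labels)}
        assert four_point_topology(full) == frozenset({"A", "B"})
        tree = neighbor_joining(DistMatrix(labels, vals))
        bipartitions = {
            frozenset(t.label for t in tree.taxon_namespace
                      if e.bipartition.leafset_bitmask
                      & tree.taxon_namespace.taxon_bitmask(t))
            for e in tree.preorder_edge_iter() if e.bipartition
        }
        assert frozenset({"A", "B"}) in bipartitions or \
            frozenset({"C", "D"}) in bipartitions
        # additive input: path lengths reproduce the matrix
        out = tree_path_distances(tree)
        assert np.allclose(out.values, vals, atol=1e-9)

    def test_three_taxa_closed_form_lengths(self):
        vals = np.array([[0.0, 0.3, 0.5],
                         [0.3, 0.0, 0.6],
                         [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistMatrix(["a", "b", "c"], vals))
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_ultrametric_four_taxa_reproduced_exactly(self):
        labels = ["a", "b", "c", "d"]
        vals = np.array([
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.4],
            [0.8, 0.8, 0.4, 0.0],
        ])
        tree = neighbor_joining(DistMatrix(labels, vals))
        out = tree_path_distances(tree)
        assert np.allclose(out.values, vals, atol=1e-9)

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_additive_matrices_recover_generating_tree(self, rng, n):
        tree = _random_tree(rng, n)
        dist = _additive_matrix_from_tree(tree)
        nj = neighbor_joining(dist)
        out = tree_path_distances(nj)
        assert out.labels == dist.labels
        assert np.allclose(out.values, dist.values, atol=1e-9)
        # independent cross-check: dendropy's own NJ agrees topologically
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            _matrix_csv(dist), is_first_row_column_names=True,
            is_first_column_row_names=True, delimiter=",",
        )
        ref = pdm.nj_tree()
        rf = dendropy.calculate.treecompare.symmetric_difference(
            *_on_common_namespace(nj, ref)
        )
        assert rf == 0

    def test_leaf_order_permutation_gives_same_topology(self, rng):
        tree = _random_tree(rng, 6)
        dist = _additive_matrix_from_tree(tree)
        perm = list(np.random.default_rng(3).permutation(len(dist.labels)))
        shuffled = DistMatrix(
            [dist.labels[i] for i in perm],
            dist.values[np.ix_(perm, perm)],
        )
        t1 = neighbor_joining(dist)
        t2 = neighbor_joining(shuffled)
        rf = dendropy.calculate.treecompare.symmetric_difference(
            *_on_common_namespace(t1, t2)
        )
        assert rf == 0

    def test_asymmetric_matrix_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = 1.0  # not mirrored
        with pytest.raises(ValueError):
            DistMatrix(["a", "b", "c"], vals)


def _matrix_csv(dist: DistMatrix) -> "io.StringIO":  # noqa: F821
    import io

    lines = ["," + ",".join(dist.labels)]
    for label, row in zip(dist.labels, dist.values):
        lines.append(label + "," + ",".join(f"{v:.10f}" for v in row))
    return io.StringIO("\n".join(lines))


def _on_common_namespace(t1, t2):
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                          schema="newick", taxon_namespace=ns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                          schema="newick", taxon_namespace=ns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return a, b


class TestCladeReport:
    def _tree(self):
        return dendropy.Tree.get(
            data="((a:1,b:1):1,(c:1,(d:1,e:1):1):1);", schema="newick")

    def test_planted_clade_is_exclusive(self):
        report = clade_report(self._tree(), {"grp": ["d", "e"]})
        row = report.iloc[0]
        assert row.exclusive
        assert row.clade_size == 2

    def test_single_leaf_trivially_exclusive(self):
        report = clade_report(self._tree(), {"solo": ["c"]})
        assert report.iloc[0].exclusive

    def test_scattered_annotation_not_exclusive(self):
        report = clade_report(self._tree(), {"split": ["a", "d"]})
        row = report.iloc[0]
        assert not row.exclusive
        assert row.clade_size > 2

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            clade_report(self._tree(), {"bad": ["zzz"]})


def test_newick_round_trip(tmp_path, rng):
    peps = [(f"p{i}", _random_peptide(rng)) for i in range(4)]
    tree = neighbor_joining(rt_distances(peps))
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    assert {t.label for t in back.taxon_namespace} == \
        {f"p{i}" for i in range(4)}
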