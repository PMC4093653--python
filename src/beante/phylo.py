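"""RT-domain distances, neighbor-joining trees, and clade reports.

Distances are p-distances from pairwise global alignment of reverse
transcriptase peptides (identities over aligned positions, terminal gaps
excluded).  The tree is built with the classic neighbor-joining algorithm
(Q-criterion minimization, Studier-Keppler updates); negative branch
estimates are clamped to zero with the clamped amount logged.  Trees are
dendropy objects and serialize to newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .align import alignment_identity, protein_aligner
from .domains import AA_ALPHABET

logger = logging.getLogger(__name__)


@dataclass
class DistMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                cells = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{label:<12s} {cells}\n")


def rt_distances(
    peptides: Mapping[str, str] | Sequence[tuple[str, str]],
) -> DistMatrix:
    """Pairwise p-distance matrix of labeled RT peptides (>= 50 aa each)."""
    items = (
        list(peptides.items()) if isinstance(peptides, Mapping)
        else list(peptides)
    )
    if len(items) < 2:
        raise ValueError("need at least two peptides")
    for label, pep in items:
        if len(pep) < 50:
            raise ValueError(f"{label}: peptide shorter than 50 aa")
        bad = set(pep) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"{label}: illegal residues {sorted(bad)}")
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    n = len(items)
    aligner = protein_aligner(mode="global")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = items[i][1], items[j][1]
            if a == b:
                continue
            alignment = aligner.align(a, b)[0]
            identity, _cols = alignment_identity(alignment, a, b)
            d[i, j] = d[j, i] = 1.0 - identity / 100.0
    return DistMatrix(labels, d)


def neighbor_joining(dist: DistMatrix) -> dendropy.Tree:
    """Classic NJ; ties in Q broken by the lexicographically smallest pair.

    Pair ordering uses each cluster's smallest descendant leaf label, so
    the result is invariant to input ordering.  Returns an unrooted
    dendropy tree with non-negative branch lengths.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("need at least three taxa")
    taxa = dendropy.TaxonNamespace(dist.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: dict[int, dendropy.Node] = {}
    tag: dict[int, str] = {}
    for i, label in enumerate(dist.labels):
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes[i] = node
        tag[i] = label
    d = {
        (i, j): float(dist.values[i, j])
        for i in range(n) for j in range(n) if i != j
    }
    active = list(range(n))
    next_id = n
    clamped = 0.0

    def dd(a: int, b: int) -> float:
        return 0.0 if a == b else d[(a, b)]

    while len(active) > 2:
        r = len(active)
        sums = {a: sum(dd(a, b) for b in active) for a in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                q = (r - 2) * dd(a, b) - sums[a] - sums[b]
                pair_key = tuple(sorted((tag[a], tag[b])))
                cand = (q, pair_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _q, _key, a, b = best
        dab = dd(a, b)
        delta = (sums[a] - sums[b]) / (r - 2)
        la = 0.5 * dab + 0.5 * delta
        lb = dab - la
        for length in (la, lb):
            if length < 0:
                clamped += -length
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        u = next_id
        next_id += 1
        nodes[u] = parent
        tag[u] = min(tag[a], tag[b])
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dd(a, c) + dd(b, c) - dab)
            d[(u, c)] = d[(c, u)] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)] + [u]

    a, b = active
    length = dd(a, b)
    root = dendropy.Node()
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    nodes[a].edge.length = length / 2.0
    nodes[b].edge.length = length - length / 2.0
    tree.seed_node = root
    tree.is_rooted = False
    if clamped:
        logger.info("clamped %.6f of negative NJ branch length", clamped)
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def tree_path_distances(tree: dendropy.Tree) -> DistMatrix:
    """Leaf-to-leaf path-length matrix of a tree (newick round-trip safe)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    values = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = values[j, i] = dist
    return DistMatrix(labels, values)


def clade_report(
    tree: dendropy.Tree,
    groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Smallest edge-bounded cluster containing each annotated leaf set.

    ``groups`` maps an annotation name to leaf labels.  A group is
    "exclusive" (monophyletic in the unrooted sense) when some edge
    bipartition separates exactly those leaves from the rest.
    """
    leaf_labels = {t.label for t in tree.taxon_namespace}
    tree.update_bipartitions(suppress_unifurcations=False)
    clusters: list[frozenset[str]] = []
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        mask = frozenset(
            t.label
            for t in tree.taxon_namespace
            if edge.bipartition.leafset_bitmask
            & tree.taxon_namespace.taxon_bitmask(t)
        )
        clusters.append(mask)
        clusters.append(frozenset(leaf_labels - mask))
    rows = []
    for name, labels in groups.items():
        labelset = frozenset(labels)
        unknown = labelset - leaf_labels
        if unknown:
            raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
        containing = [c for c in clusters if labelset <= c and c]
        smallest = min(containing, key=len) if containing else labelset
        rows.append(dict(
            annotation=name,
            n_annotated=len(labelset),
            clade_size=len(smallest),
            exclusive=len(smallest) == len(labelset),
        ))
    return pd.DataFrame(
        rows, columns=["annotation", "n_annotated", "clade_size",
                       "exclusive"],
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
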