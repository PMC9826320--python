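"""Phylogenetic trees, Grafen branch lengths and the species correlation matrix.

The meta-analytic models treat shared ancestry as a random-effect correlation
structure: species effects are jointly normal with correlation matrix A, where
A[i, j] is the fraction of the root-to-tip path that species i and j share.
Published bird phylogenies often lack usable branch lengths, so node heights
are first assigned by Grafen's method — each internal node's height is its
number of descendant tips minus one, raised to a power rho (default 1) and
scaled so the root has height 1 — which yields an ultrametric tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


@dataclass
class PhyloCorrelation:
    """Species-by-species correlation matrix with its species ordering."""

    species: list[str]
    matrix: np.ndarray

    def submatrix(self, species: list[str]) -> "PhyloCorrelation":
        """Correlation matrix restricted (and reordered) to ``species``."""
        missing = [s for s in species if s not in self.species]
        if missing:
            raise KeyError(f"species absent from correlation matrix: {missing}")
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelation(list(species), self.matrix[np.ix_(idx, idx)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.species, columns=self.species).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PhyloCorrelation":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def read_newick(source) -> dendropy.Tree:
    """Parse a rooted Newick tree from a string or a file path."""
    try:
        if isinstance(source, str) and source.lstrip().startswith(("(", "[")):
            tree = dendropy.Tree.get(data=source, schema="newick")
        elif hasattr(source, "read"):
            tree = dendropy.Tree.get(file=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=str(source), schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderError as exc:
        raise ValueError(f"invalid Newick input: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels in tree: {sorted(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick").strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def grafen_lengths(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Assign Grafen branch lengths in place (and return the tree).

    Each node's height is (number of descendant tips - 1) ** rho, scaled so
    the root height is 1; tips sit at height 0 and every branch length is
    parent height minus child height, so the result is ultrametric.
    Polytomies are handled natively — heights depend only on tip counts.
    """
    tips = len(tree.leaf_nodes())
    if tips < 2:
        raise ValueError("Grafen heights need at least 2 tips")
    root_raw = float(tips - 1) ** rho
    for node in tree.postorder_node_iter():
        n_desc = len(node.leaf_nodes()) if not node.is_leaf() else 1
        height = 0.0 if node.is_leaf() else float(n_desc - 1) ** rho / root_raw
        node.grafen_height = height
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.grafen_height - node.grafen_height
    if tree.seed_node.edge is not None:
        tree.seed_node.edge.length = 0.0
    return tree


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depths[node] = (depths[parent] if parent is not None else 0.0) + (
            edge if parent is not None else 0.0
        )
    return depths


def phylo_correlation(tree: dendropy.Tree, atol: float = 1e-8) -> PhyloCorrelation:
    """Species correlation matrix from an ultrametric tree with branch lengths.

    A[i, j] is the root-to-MRCA(i, j) path length divided by the total tree
    depth; the diagonal is 1. Requires an ultrametric tree — otherwise
    shared-path fractions are not a valid correlation.
    """
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    tip_depths = np.array([depths[l] for l in leaves])
    total = tip_depths.mean()
    if total <= 0:
        raise ValueError("tree has zero depth; assign branch lengths first")
    if np.any(np.abs(tip_depths - total) > atol * max(1.0, total)):
        raise ValueError("tree is not ultrametric; correlations are ill-defined")
    labels = [l.taxon.label for l in leaves]
    n = len(leaves)
    index = {l: i for i, l in enumerate(leaves)}
    A = np.eye(n)
    # For each internal node, tip pairs split across different children have
    # that node as MRCA; fill them with the node's depth fraction.
    for node in tree.postorder_internal_node_iter():
        frac = depths[node] / total
        children = node.child_nodes()
        groups = [[index[t] for t in ch.leaf_nodes()] for ch in children]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    A[i, groups[b]] = frac
                    A[np.ix_(groups[b], [i])] = frac
    return PhyloCorrelation(labels, A)


def correlation_from_newick(source, rho: float = 1.0) -> PhyloCorrelation:
    """Convenience: parse, assign Grafen lengths, and build the A matrix."""
    return phylo_correlation(grafen_lengths(read_newick(source), rho=rho))
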