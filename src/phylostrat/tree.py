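"""Ultrametric time-tree container.

A thin array-backed wrapper around a rooted tree whose branch lengths are in
millions of years (MY).  Leaves sit at age 0 and every internal node carries
the age of the divergence it represents.  Construction goes through dendropy
for newick parsing/writing; queries used heavily by the pipeline (MRCA, Dollo
loss counting, vectorized random-subset nulls) run on flat numpy arrays.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["TimeTree"]


class TimeTree:
    """Rooted ultrametric tree with node ages in MY.

    Parameters
    ----------
    parent:
        Parent index per node (-1 for the root).  Children must have higher
        indices than their parents (topological order).
    age:
        Node ages in MY; 0 for leaves, strictly increasing toward the root.
    leaf_names:
        Taxon label for each leaf node index, as ``{name: node_index}``.
    """

    def __init__(
        self, parent: Sequence[int], age: Sequence[float], leaf_names: dict[str, int]
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.age = np.asarray(age, dtype=float)
        self.n_nodes = self.parent.size
        self.leaf_index = dict(leaf_names)
        self.leaf_names = sorted(self.leaf_index)
        is_leaf = np.ones(self.n_nodes, dtype=bool)
        for p in self.parent:
            if p >= 0:
                is_leaf[p] = False
        self.is_leaf = is_leaf
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        # children lists and a child-before-parent (reverse topological) order
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(i)
        self.children = children
        self.postorder = np.argsort(-np.arange(self.n_nodes))  # reversed index order
        self._validate()
        # leaf membership per node as a (n_nodes, n_leaves) boolean matrix;
        # small trees only (hundreds of leaves), so this is cheap and makes
        # subset queries vectorizable.
        self._leaf_cols = {name: j for j, name in enumerate(self.leaf_names)}
        below = np.zeros((self.n_nodes, len(self.leaf_names)), dtype=bool)
        for name, idx in self.leaf_index.items():
            below[idx, self._leaf_cols[name]] = True
        for i in self.postorder:
            p = self.parent[i]
            if p >= 0:
                below[p] |= below[i]
        self.leaves_below = below

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        """Parse a newick string whose branch lengths are in MY."""
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    @classmethod
    def from_file(cls, path) -> "TimeTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TimeTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        depth = np.zeros(len(nodes))
        leaf_names: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValueError("newick tree must carry branch lengths (MY)")
                depth[i] = depth[parent[i]] + nd.edge.length
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("every leaf must be labeled")
                name = nd.taxon.label.replace(" ", "_")
                if name in leaf_names:
                    raise ValueError(f"duplicate leaf name {name!r}")
                leaf_names[name] = i
        leaf_depths = np.array([depth[i] for i in leaf_names.values()])
        height = leaf_depths.max()
        if leaf_depths.size and (height - leaf_depths.min()) > 1e-6 * max(height, 1.0):
            raise ValueError("tree is not ultrametric: leaves at unequal depths")
        age = height - depth
        age[np.array([i for i in leaf_names.values()])] = 0.0
        return cls(parent, age, leaf_names)

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.is_leaf[i]:
                name = next(n for n, j in self.leaf_index.items() if j == i)
                bl = self.age[self.parent[i]] - self.age[i]
                return f"{name}:{bl:.6f}"
            inner = ",".join(fmt(c) for c in self.children[i])
            if self.parent[i] < 0:
                return f"({inner});"
            bl = self.age[self.parent[i]] - self.age[i]
            return f"({inner}):{bl:.6f}"

        return fmt(self.root)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -------------------------------------------------------------- queries
    def _validate(self) -> None:
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                if p >= i:
                    raise ValueError("nodes must be in topological order")
                if self.age[p] <= self.age[i] - 1e-9:
                    raise ValueError("parent age must exceed child age")
        if not np.allclose(self.age[self.is_leaf], 0.0, atol=1e-6):
            raise ValueError("tree is not ultrametric (leaf ages must be 0)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def presence_vector(self, species: Iterable[str]) -> np.ndarray:
        """Boolean leaf-membership vector (in leaf-name sorted order)."""
        vec = np.zeros(self.n_leaves, dtype=bool)
        for sp in species:
            try:
                vec[self._leaf_cols[sp]] = True
            except KeyError:
                raise KeyError(f"species {sp!r} not on the tree") from None
        return vec

    def subtree_counts(self, presence: np.ndarray) -> np.ndarray:
        """Number of presence leaves below each node (vector or matrix form).

        ``presence`` may be a single boolean vector of length ``n_leaves`` or
        a ``(reps, n_leaves)`` matrix; the result has a matching leading shape
        with one count per node.
        """
        arr = np.asarray(presence)
        single = arr.ndim == 1
        counts = np.atleast_2d(arr).astype(np.int32) @ self.leaves_below.T.astype(np.int32)
        return counts[0] if single else counts

    def mrca(self, species: Iterable[str]) -> int:
        """Node index of the most recent common ancestor of ``species``."""
        vec = self.presence_vector(species)
        k = int(vec.sum())
        if k == 0:
            raise ValueError("presence set is empty")
        counts = np.atleast_2d(self.subtree_counts(vec))[0]
        # deepest (largest index in preorder ~ smallest subtree) node holding all k
        candidates = np.flatnonzero(counts == k)
        return int(candidates.max())

    def mrca_age(self, species: Iterable[str]) -> float:
        return float(self.age[self.mrca(species)])

    def parent_age(self, node: int) -> float | None:
        p = self.parent[node]
        return None if p < 0 else float(self.age[p])
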