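"""Rooted phylogenetic trees with array-backed traversal.

Trees are parsed from Newick with :mod:`dendropy` and converted to a compact
array representation: nodes carry integer IDs assigned in preorder (root is 0,
parents precede children), which makes branch enumeration, traversal order and
downstream permutation seeding deterministic across runs. Internal-node labels
found in Newick (names or support values) are kept as annotations and never
used as identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Branch",
    "PhyloTree",
    "NewickParseError",
    "TreeError",
    "read_newick",
    "enumerate_branches",
    "patristic_distance",
]


class NewickParseError(ValueError):
    """Raised when Newick input cannot be parsed or violates tree invariants."""


class TreeError(ValueError):
    """Raised for structurally invalid trees or unknown labels."""


@dataclass(frozen=True)
class Branch:
    """A branch, identified by its child node; the root has no incoming branch."""

    parent: int
    child: int
    length: float


class PhyloTree:
    """Rooted tree over nodes ``0..n_nodes-1`` in preorder (root is node 0).

    Parameters
    ----------
    parent
        ``parent[i]`` is the preorder ID of node *i*'s parent; ``-1`` for the
        root. Parents must precede children (``parent[i] < i`` for ``i > 0``).
    lengths
        Branch length of the branch above each node (ignored for the root).
        Lengths must be nonnegative; zero-length branches are permitted.
    labels
        Per-node label; required (and unique) for tips, optional elsewhere.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
        annotations: Sequence[str | None] | None = None,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64).copy()
        n = self.parent.size
        if n == 0:
            raise TreeError("empty tree")
        if self.parent[0] != -1:
            raise TreeError("node 0 must be the root (parent -1)")
        if n > 1 and not np.all(self.parent[1:] < np.arange(1, n)):
            raise TreeError("parents must precede children (preorder IDs)")
        if np.any(self.lengths[1:] < 0):
            bad = int(np.flatnonzero(self.lengths[1:] < 0)[0]) + 1
            raise TreeError(f"negative branch length on node {bad}")
        self.lengths[0] = 0.0
        self.labels = list(labels)
        self.annotations = list(annotations) if annotations is not None else [None] * n

        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.tip_ids = np.array(
            [i for i in range(n) if not self.children[i]], dtype=np.int64
        )
        tips = [self.labels[i] for i in self.tip_ids]
        if any(t is None for t in tips):
            raise TreeError("every tip must carry a label")
        if len(set(tips)) != len(tips):
            seen: set[str] = set()
            dup = next(t for t in tips if t in seen or seen.add(t))  # type: ignore[func-returns-value]
            raise NewickParseError(f"duplicate tip label: {dup!r}")
        self.tip_labels: list[str] = tips  # in preorder
        self._tip_index = {lab: int(i) for lab, i in zip(tips, self.tip_ids)}
        if len(self.children[0]) > 2:
            logger.warning(
                "root has %d children: tree looks unrooted; proceeding as-is",
                len(self.children[0]),
            )

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tip_ids.size

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def preorder(self) -> range:
        return range(self.n_nodes)

    def postorder(self) -> range:
        # reversed preorder visits children before parents
        return range(self.n_nodes - 1, -1, -1)

    def branches(self) -> list[Branch]:
        """One branch per non-root node, ordered by child ID (preorder)."""
        return [
            Branch(int(self.parent[i]), i, float(self.lengths[i]))
            for i in range(1, self.n_nodes)
        ]

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"unknown tip label: {label!r}") from None

    # -------------------------------------------------------------- distances
    def node_depths(self) -> np.ndarray:
        """Cumulative branch length from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + self.lengths[i]
        return depth

    def patristic_distance(self, tip_a: str, tip_b: str) -> float:
        a, b = self.tip_id(tip_a), self.tip_id(tip_b)
        if a == b:
            return 0.0
        depth = self.node_depths()
        anc_a = set()
        u = a
        while u != -1:
            anc_a.add(u)
            u = int(self.parent[u])
        u = b
        while u not in anc_a:
            u = int(self.parent[u])
        return float(depth[a] + depth[b] - 2.0 * depth[u])

    def tip_distance_matrix(self) -> np.ndarray:
        """Pairwise patristic distances, ordered as ``tip_labels``."""
        n = self.n_nodes
        depth = self.node_depths()
        # ancestor sets as sorted arrays of node ids, root-first
        paths: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            paths[i] = ([] if i == 0 else paths[self.parent[i]]) + [i]
        k = self.n_tips
        out = np.zeros((k, k))
        for ia in range(k):
            pa = paths[self.tip_ids[ia]]
            sa = set(pa)
            for ib in range(ia + 1, k):
                pb = paths[self.tip_ids[ib]]
                lca = 0
                for node in reversed(pb):
                    if node in sa:
                        lca = node
                        break
                d = depth[self.tip_ids[ia]] + depth[self.tip_ids[ib]] - 2 * depth[lca]
                out[ia, ib] = out[ib, ia] = d
        return out

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        if not text or not text.strip():
            raise NewickParseError("empty Newick input")
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        if dtree.seed_node is None or not dtree.seed_node.child_nodes():
            if dtree.seed_node is None:
                raise NewickParseError("empty Newick input")
        order = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(order)}
        parent, lengths, labels, annots = [], [], [], []
        for nd in order:
            parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
            lengths.append(float(nd.edge.length) if nd.edge.length is not None else 0.0)
            if nd.is_leaf():
                lab = nd.taxon.label if nd.taxon is not None else nd.label
                if lab is None:
                    raise NewickParseError("tip without a label")
                labels.append(str(lab))
                annots.append(None)
            else:
                labels.append(None)
                annots.append(None if nd.label is None else str(nd.label))
        return cls(parent, lengths, labels, annots)

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.is_tip(i):
                core = self.labels[i]
            else:
                inner = ",".join(fmt(c) for c in self.children[i])
                ann = self.annotations[i] or ""
                core = f"({inner}){ann}"
            if i == 0:
                return core
            return f"{core}:{self.lengths[i]:.10g}"

        return fmt(0) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def enumerate_branches(tree: PhyloTree) -> list[Branch]:
    """All non-root branches in deterministic preorder-by-child-ID order."""
    return tree.branches()


def patristic_distance(tree: PhyloTree, tip_a: str, tip_b: str) -> float:
    """Sum of branch lengths on the unique path between two tips."""
    return tree.patristic_distance(tip_a, tip_b)
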