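"""Rooted binary time trees with node ages in calendar years before present.

Ages increase into the past: a "modern" tip has age 0 and the root is the
oldest node.  Branch lengths, wherever serialized, are in years
(``parent_age - child_age``); substitution-scaled trees are never written.

The internal representation is array-based for fast use inside the MCMC
sampler: nodes ``0 .. n_tips-1`` are tips (carrying labels), nodes
``n_tips .. 2*n_tips-2`` are internal, and topology is held in a single
``parent`` array.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

from .errors import FormatError, TreeConstraintError

NO_PARENT = -1


class TimeTree:
    """A rooted binary genealogy with per-node ages (years BP).

    Parameters
    ----------
    parent : array of int, length 2*n_tips - 1
        ``parent[i]`` is the parent index of node i, or -1 for the root.
        Tips occupy indices ``0..n_tips-1``.
    ages : array of float, same length
        Node ages in years before present.
    labels : sequence of str, length n_tips
        Tip labels, unique.
    """

    def __init__(self, parent: Sequence[int], ages: Sequence[float], labels: Sequence[str]):
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        self.ages = np.asarray(ages, dtype=float).copy()
        self.labels = list(labels)
        self.n_tips = len(self.labels)
        self._postorder: np.ndarray | None = None
        self._children: dict[int, list[int]] | None = None
        self.topology_version = 0  # bumped on every topology change
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent == NO_PARENT)
        if len(roots) != 1:
            raise TreeConstraintError(f"tree must have exactly one root, found {len(roots)}")
        return int(roots[0])

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def children_map(self) -> dict[int, list[int]]:
        if self._children is None:
            cm: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
            for i, p in enumerate(self.parent):
                if p != NO_PARENT:
                    cm[int(p)].append(i)
            self._children = cm
        return self._children

    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents (topology-cached)."""
        if self._postorder is None:
            cm = self.children_map()
            order: list[int] = []
            stack = [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(cm[node])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def invalidate_topology(self) -> None:
        """Call after mutating ``parent`` in place."""
        self._postorder = None
        self._children = None
        self.topology_version += 1

    def copy(self) -> "TimeTree":
        return TimeTree(self.parent, self.ages, self.labels)

    def tip_ages(self) -> dict[str, float]:
        return {lab: float(self.ages[i]) for i, lab in enumerate(self.labels)}

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        n = self.n_tips
        if n < 2:
            raise TreeConstraintError("a time tree needs at least 2 tips")
        if len(set(self.labels)) != n:
            raise TreeConstraintError("tip labels must be unique")
        if self.parent.shape != (2 * n - 1,) or self.ages.shape != (2 * n - 1,):
            raise TreeConstraintError("parent/ages arrays must have length 2*n_tips-1")
        if np.any(self.ages[:n] < 0):
            raise TreeConstraintError("tip ages must be >= 0")
        root = self.root  # also checks uniqueness
        cm = self.children_map()
        for node in range(n, self.n_nodes):
            kids = cm[node]
            if len(kids) != 2:
                raise TreeConstraintError(f"internal node {node} has {len(kids)} children (binary required)")
            for c in kids:
                if self.ages[node] <= self.ages[c]:
                    raise TreeConstraintError(
                        f"internal node {node} (age {self.ages[node]:g}) is not strictly "
                        f"older than its child {c} (age {self.ages[c]:g})"
                    )
        if self.ages[root] < self.ages.max():
            raise TreeConstraintError("root must be the oldest node")
        if np.any(self.parent[:n] == NO_PARENT):
            raise TreeConstraintError("tips cannot be the root")

    # -- newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, tip_ages: dict[str, float] | None = None) -> "TimeTree":
        """Parse a newick string whose branch lengths are in years.

        Branch lengths fix only relative node times; absolute ages are
        anchored so that the tip farthest from the root has age 0, unless
        ``tip_ages`` supplies the true age of at least one tip (all supplied
        ages must then be mutually consistent with the branch lengths).
        """
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"malformed newick: {exc}") from exc

        leaves = [lf for lf in dtree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon is not None else "" for lf in leaves]
        if any(not lab for lab in labels):
            raise FormatError("every tip must be labelled")
        n = len(labels)

        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        next_internal = n
        for node in dtree.preorder_node_iter():
            if node.is_leaf():
                continue
            if len(node.child_nodes()) != 2:
                raise FormatError("tree must be strictly bifurcating (rooted binary)")
            index[id(node)] = next_internal
            next_internal += 1
        if next_internal != 2 * n - 1:
            raise FormatError("unexpected node count for a binary tree")

        parent = np.full(2 * n - 1, NO_PARENT, dtype=np.int64)
        depth = np.zeros(2 * n - 1, dtype=float)
        for node in dtree.preorder_node_iter():
            i = index[id(node)]
            if node.parent_node is not None:
                parent[i] = index[id(node.parent_node)]
                edge = node.edge.length if node.edge.length is not None else 0.0
                if edge < 0:
                    raise FormatError("negative branch length")
                depth[i] = depth[parent[i]] + edge

        if tip_ages:
            offsets = []
            for i, lab in enumerate(labels):
                if lab in tip_ages:
                    offsets.append(tip_ages[lab] + depth[i])
            if not offsets:
                raise FormatError("tip_ages provided but none match the tree's tips")
            offset = offsets[0]
            if max(offsets) - min(offsets) > 1e-6 * max(1.0, abs(offset)):
                raise FormatError("supplied tip ages are inconsistent with branch lengths")
        else:
            offset = depth[:n].max()
        ages = offset - depth
        scale = max(1.0, abs(offset))
        # clamp float-roundoff negatives at the present
        ages[:n][(ages[:n] < 0) & (ages[:n] > -1e-6 * scale)] = 0.0
        # zero-length internal edges would tie parent and child ages; nudge
        # ancestors up by an infinitesimal amount so ordering stays strict
        eps = 1e-9 * scale
        children: dict[int, list[int]] = {i: [] for i in range(2 * n - 1)}
        for i, p in enumerate(parent):
            if p != NO_PARENT:
                children[int(p)].append(i)

        def fix(node: int) -> None:
            for c in children[node]:
                fix(c)
            if children[node]:
                top = max(ages[c] for c in children[node])
                if ages[node] <= top:
                    ages[node] = top + eps

        fix(int(np.flatnonzero(parent == NO_PARENT)[0]))
        return cls(parent, ages, labels)

    def to_newick(self, precision: int = 10) -> str:
        """Serialize with branch lengths in years."""
        cm = self.children_map()

        def fmt(x: float) -> str:
            return f"{x:.{precision}f}".rstrip("0").rstrip(".") or "0"

        def build(node: int) -> str:
            if node < self.n_tips:
                return self.labels[node]
            a, b = cm[node]
            la = self.ages[node] - self.ages[a]
            lb = self.ages[node] - self.ages[b]
            return f"({build(a)}:{fmt(la)},{build(b)}:{fmt(lb)})"

        return build(self.root) + ";"

    def __repr__(self) -> str:
        return f"<TimeTree n_tips={self.n_tips} root_age={self.root_age:.1f}>"


def read_tree(path, tip_ages: dict[str, float] | None = None) -> TimeTree:
    with open(path) as fh:
        return TimeTree.from_newick(fh.read(), tip_ages=tip_ages)


def write_tree(tree: TimeTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
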