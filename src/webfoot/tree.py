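"""Rooted phylogenetic trees as flat parent/child arrays.

Trees come in as Newick text (parsed with dendropy) and are flattened into
index-based arrays, which is what the pruning likelihood wants. Polytomies
are kept as-is; missing branch lengths default to 1, matching the "unscaled
tree" convention where the topology is analysed with unit branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import NewickParseError, ValidationError

__all__ = ["PhyloTree", "read_newick", "write_newick"]


@dataclass
class PhyloTree:
    """A rooted tree over nodes 0..n-1.

    Parameters
    ----------
    parent : array of int
        ``parent[v]`` is the parent index of node v, or -1 for the root.
    branch_lengths : array of float
        Length of the branch above each node, in expected substitutions per
        character; the root's entry is ignored.
    labels : list of str or None
        Tip labels (required, unique); internal labels optional.
    root : int
        Index of the unique root node.
    """

    parent: np.ndarray
    branch_lengths: np.ndarray
    labels: list
    root: int
    children: list = field(default=None, repr=False)
    postorder: np.ndarray = field(default=None, repr=False)
    preorder: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        n = self.parent.size
        if self.branch_lengths.size != n or len(self.labels) != n:
            raise ValidationError("parent, branch_lengths and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1 or roots[0] != self.root:
            raise ValidationError("tree must have exactly one root (parent == -1)")
        self.children = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        # connectivity / acyclicity: iterative DFS from the root must visit all
        order = []
        stack = [self.root]
        seen = np.zeros(n, dtype=bool)
        while stack:
            v = stack.pop()
            if seen[v]:
                raise ValidationError("tree contains a cycle")
            seen[v] = True
            order.append(v)
            stack.extend(reversed(self.children[v]))
        if not seen.all():
            raise ValidationError("tree is not connected")
        self.preorder = np.array(order, dtype=int)
        self.postorder = self.preorder[::-1].copy()
        bad = [v for v in range(n) if v != self.root and not self.branch_lengths[v] > 0]
        if bad:
            raise ValidationError(f"non-root branch lengths must be > 0 (nodes {bad})")
        tips = self.tips
        tip_labels = [self.labels[v] for v in tips]
        if any(lb is None for lb in tip_labels):
            raise ValidationError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            dup = sorted({lb for lb in tip_labels if tip_labels.count(lb) > 1})
            raise ValidationError(f"duplicate tip labels: {dup}")

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def tips(self) -> np.ndarray:
        return np.array([v for v in range(self.n_nodes) if not self.children[v]], dtype=int)

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.array([v for v in range(self.n_nodes) if self.children[v]], dtype=int)

    @property
    def n_tips(self) -> int:
        return self.tips.size

    @property
    def tip_labels(self) -> list:
        return [self.labels[v] for v in self.tips]

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    def node_name(self, v: int) -> str:
        """Stable display name: the label if present, else ``N{index}``."""
        return self.labels[v] if self.labels[v] else f"N{v}"

    def with_unit_branch_lengths(self) -> "PhyloTree":
        bl = np.ones(self.n_nodes)
        return PhyloTree(self.parent.copy(), bl, list(self.labels), self.root)

    def newick(self, annotations=None, branch_lengths=True) -> str:
        return write_newick(self, annotations=annotations, branch_lengths=branch_lengths)


def read_newick(text: str, force_unit_lengths: bool = False, default_length: float = 1.0) -> PhyloTree:
    """Parse one Newick tree into a :class:`PhyloTree`.

    Absent branch lengths default to ``default_length`` (1, the unscaled-tree
    convention); ``force_unit_lengths`` overrides any lengths present so that
    alternative topologies with published lengths can be rerun unscaled.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error classes
        if "uplicate" in str(exc):
            raise ValidationError(f"duplicate tip labels: {exc}") from None
        raise NewickParseError(f"malformed Newick: {exc}") from None

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=int)
    bl = np.full(n, float(default_length))
    labels = [None] * n
    for i, nd in enumerate(dnodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
        if nd.edge.length is not None and nd.parent_node is not None:
            bl[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    if force_unit_lengths:
        bl[:] = 1.0
    tree = PhyloTree(parent, bl, labels, root=index[id(dtree.seed_node)])
    if tree.n_tips < 1:
        raise NewickParseError("tree has no tips")
    return tree


def _fmt_length(x: float) -> str:
    s = f"{x:.12g}"
    return s


def write_newick(tree: PhyloTree, annotations=None, branch_lengths=True) -> str:
    """Serialise to Newick; ``annotations`` maps node index -> comment string
    (emitted verbatim in square brackets after the node label)."""
    annotations = annotations or {}

    def rec(v: int) -> str:
        if tree.is_tip(v):
            out = tree.labels[v]
        else:
            out = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
            if tree.labels[v]:
                out += tree.labels[v]
        if v in annotations:
            out += f"[{annotations[v]}]"
        if branch_lengths and tree.parent[v] >= 0:
            out += ":" + _fmt_length(tree.branch_lengths[v])
        return out

    return rec(tree.root) + ";"
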