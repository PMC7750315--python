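"""Rooted time-calibrated trees: Newick IO (via dendropy) and array accessors.

The comparative methods work on a lightweight array representation: nodes are
indexed with tips first (0..n_tips-1) followed by internal nodes in postorder,
the root last.  ``parent``/``blen`` arrays and a postorder index make pruning
recursions and Brownian covariance construction cheap and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .errors import TreeError

__all__ = ["PhyloTree", "read_newick", "write_newick"]


@dataclass
class PhyloTree:
    """Rooted binary-or-multifurcating tree with branch lengths in time units."""

    tip_labels: list[str]
    parent: np.ndarray  # parent index per node; -1 at the root
    blen: np.ndarray    # branch length above each node; 0 at the root
    children: list[list[int]]

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise TreeError("duplicate tip labels")
        if np.any(self.blen < 0):
            raise TreeError("negative branch lengths")

    # -- derived structure ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    @property
    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return np.array(order[::-1], dtype=int)

    @property
    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    def depths(self) -> np.ndarray:
        """Time from the root to each node."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder:
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.blen[node]
        return d

    @property
    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        tip_d = self.depths()[: self.n_tips]
        h = tip_d.max()
        return bool(h == 0 or np.all(np.abs(tip_d - h) <= rel_tol * h))

    def vcv(self) -> np.ndarray:
        """Brownian covariance structure: shared root-to-MRCA path lengths."""
        n = self.n_tips
        depths = self.depths()
        C = np.zeros((n, n))
        tipsets: dict[int, list[int]] = {}
        for node in self.postorder:
            if node < n:
                tipsets[node] = [node]
                C[node, node] = depths[node]
            else:
                kids = self.children[node]
                merged: list[int] = []
                for a_i in range(len(kids)):
                    for b_i in range(a_i + 1, len(kids)):
                        for i in tipsets[kids[a_i]]:
                            for j in tipsets[kids[b_i]]:
                                C[i, j] = C[j, i] = depths[node]
                for k in kids:
                    merged.extend(tipsets.pop(k))
                tipsets[node] = merged
        return C

    def mrca_depths(self) -> np.ndarray:
        return self.vcv()

    def tip_index(self, labels) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.tip_labels)}
        try:
            return np.array([lookup[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise TreeError(f"tip label not in tree: {exc.args[0]!r}") from exc

    def rescale(self, height: float) -> "PhyloTree":
        h = self.height
        if h <= 0:
            raise TreeError("cannot rescale a zero-height tree")
        return PhyloTree(
            tip_labels=list(self.tip_labels),
            parent=self.parent.copy(),
            blen=self.blen * (height / h),
            children=[list(c) for c in self.children],
        )

    # -- serialization -------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            if node < self.n_tips:
                core = self.tip_labels[node]
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[node]) + ")"
            if self.parent[node] == -1:
                return core
            return f"{core}:{self.blen[node]:.10g}"

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    leaves = [lf for lf in dtree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
    if any(lab is None for lab in labels):
        raise TreeError("unlabelled tip")
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate tip labels")
    internal = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
    index = {id(nd): i for i, nd in enumerate(leaves)}
    for off, nd in enumerate(internal):
        index[id(nd)] = len(leaves) + off

    n_nodes = len(leaves) + len(internal)
    parent = np.full(n_nodes, -1, dtype=int)
    blen = np.zeros(n_nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for nd in dtree.preorder_node_iter():
        i = index[id(nd)]
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                raise TreeError("missing branch length")
            blen[i] = float(nd.edge.length)
    return PhyloTree(tip_labels=labels, parent=parent, blen=blen, children=children)


def read_newick(source: str | Path) -> PhyloTree:
    """Parse a Newick tree from a path or a literal Newick string."""
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text()
    elif isinstance(source, str) and source.strip().endswith(";"):
        text = source
    else:
        raise TreeError(f"cannot read tree from {source!r}")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"newick parse failure: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree, path) -> None:
    tree.write(path)
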