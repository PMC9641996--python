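"""Rooted trees with branch lengths.

A thin array-backed representation tuned for pruning-style dynamic
programming: nodes are integer indices, ``parent[i]`` points upward
(-1 at the root), and ``postorder`` lists children before parents.
Newick parsing/serialisation is delegated to :mod:`dendropy`.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import dendropy
import numpy as np

__all__ = ["Tree"]


class Tree:
    """Rooted tree with branch lengths and unique tip labels.

    Parameters
    ----------
    parent:
        Parent index per node, ``-1`` for the root.
    blen:
        Branch length above each node (ignored at the root).
    labels:
        Node labels; tips must be uniquely labelled, internal labels
        are optional (``None`` allowed).
    """

    def __init__(
        self,
        parent: Sequence[int],
        blen: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=np.float64)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.blen) == len(self.labels) == n):
            raise ValueError("parent, blen and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        if np.any(self.blen[np.arange(n) != self.root] < 0):
            raise ValueError("negative branch length")
        self.postorder = self._postorder()
        tips = self.tip_indices
        tip_labels = [self.labels[i] for i in tips]
        if any(lab is None for lab in tip_labels):
            raise ValueError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            raise ValueError("tip labels must be unique")

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    def _postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        # verify acyclicity: every node reached exactly once
        if len(order) != len(self.parent) or len(set(order)) != len(order):
            raise ValueError("tree contains a cycle or disconnected nodes")
        return np.asarray(order, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def internal_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]  # type: ignore[misc]

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def is_binary(self) -> bool:
        return all(len(self.children[i]) == 2 for i in self.internal_indices)

    def preorder(self) -> Iterator[int]:
        return iter(self.postorder[::-1])

    def node_label(self, i: int) -> str:
        lab = self.labels[i]
        return lab if lab is not None else f"nd{i}"

    # ------------------------------------------------------------------
    # metrics
    # ------------------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.blen[v]
        return d

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths()[self.tip_indices]
        span = d.max() - d.min()
        return bool(span <= rel_tol * max(d.max(), 1.0))

    def total_length(self) -> float:
        mask = np.arange(self.n_nodes) != self.root
        return float(self.blen[mask].sum())

    def mrca_depths(self) -> np.ndarray:
        """Shared-path matrix C over tips: C[i,j] = depth of MRCA(i,j).

        Diagonal holds the root-to-tip distance. Tip order follows
        :attr:`tip_labels`.
        """
        tips = self.tip_indices
        ntips = len(tips)
        depth = self.depths()
        # tip sets below each node, computed in postorder
        below: dict[int, list[int]] = {}
        tip_pos = {t: i for i, t in enumerate(tips)}
        C = np.zeros((ntips, ntips))
        for v in self.postorder:
            if self.is_tip(v):
                below[v] = [tip_pos[v]]
                C[tip_pos[v], tip_pos[v]] = depth[v]
            else:
                kids = [below[c] for c in self.children[v]]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                C[i, j] = C[j, i] = depth[v]
                merged: list[int] = []
                for kk in kids:
                    merged.extend(kk)
                below[v] = merged
        return C

    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance structure of the tips (unit rate)."""
        return self.mrca_depths()

    def copy(self) -> "Tree":
        return Tree(self.parent.copy(), self.blen.copy(), list(self.labels))

    # ------------------------------------------------------------------
    # Newick IO
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls._from_dendropy(dt)

    @classmethod
    def read(cls, path: str, schema: str = "newick") -> "Tree":
        dt = dendropy.Tree.get(path=str(path), schema=schema)
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "Tree":
        nodes = list(dt.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, blen, labels = [], [], []
        for nd in nodes:
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            blen.append(nd.edge.length if nd.edge.length is not None else 0.0)
            if nd.taxon is not None:
                labels.append(nd.taxon.label)
            else:
                labels.append(nd.label)
        return cls(parent, blen, labels)

    def to_newick(self, internal_labels: bool = False) -> str:
        def render(v: int) -> str:
            if self.is_tip(v):
                core = _quote(self.labels[v] or "")
            else:
                inner = ",".join(render(c) for c in self.children[v])
                lab = self.labels[v] if internal_labels and self.labels[v] else ""
                core = f"({inner}){_quote(lab) if lab else ''}"
            if v == self.root:
                return core
            return f"{core}:{self.blen[v]:.10g}"

        return render(self.root) + ";"

    def write(self, path: str, internal_labels: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(internal_labels=internal_labels) + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {self.n_tips} tips, {self.n_nodes} nodes>"


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label
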