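"""Neighbor-joining lineage trees over clonal sequence variants.

Variants are projected onto germline coordinates (gap-free for the
substitution-only data model), pairwise Hamming distances computed, and a
Saitou-Nei neighbor-joining tree built with deterministic tie-breaking.
Leaf labels carry read counts (``v<rank>_<count>``) so the rendered tree shows
the abundance of every variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is asymmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def n_edges(self) -> int:
        total = 0
        for child, _ in self.children:
            total += 1 + child.n_edges()
        return total


@dataclass
class LineageTree:
    """Unrooted tree, stored rooted at a trifurcating internal node."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def n_edges(self) -> int:
        return self.root.n_edges()

    def to_newick(self) -> str:
        return _write_newick(self.root) + ";"

    def path_length_matrix(self, labels: Sequence[str]) -> np.ndarray:
        """Leaf-to-leaf path lengths in the order of ``labels``."""
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[str, int] = {}
        counter = [0]

        def build(node: TreeNode) -> int:
            nid = counter[0]
            counter[0] += 1
            adj.setdefault(nid, [])
            if node.is_leaf:
                names[node.name] = nid
            for child, length in node.children:
                cid = build(child)
                adj[nid].append((cid, length))
                adj[cid].append((nid, length))
            return nid

        build(self.root)
        n = len(labels)
        out = np.zeros((n, n))
        for i, label in enumerate(labels):
            dist = {names[label]: 0.0}
            stack = [names[label]]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, other in enumerate(labels):
                out[i, j] = dist[names[other]]
        return out

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (as the smaller-side leaf set by value of
        min(side, complement) canonicalization) — topology comparison aid."""
        all_leaves = frozenset(self.leaf_names())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 1 < len(side) < len(all_leaves) - 1:
                    other = all_leaves - side
                    out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
                below |= side
            return below

        walk(self.root)
        return out


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def _write_newick(node: TreeNode) -> str:
    if node.is_leaf:
        return node.name or ""
    inner = ",".join(
        f"{_write_newick(child)}:{_fmt_len(length)}" for child, length in node.children
    )
    return f"({inner})"


def parse_newick(text: str) -> LineageTree:
    """Minimal Newick parser (names, branch lengths; no quoting/comments)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = text[:-1]
    pos = [0]

    def parse_node() -> TreeNode:
        node = TreeNode()
        if pos[0] < len(s) and s[pos[0]] == "(":
            pos[0] += 1
            while True:
                child = parse_node()
                length = 0.0
                if pos[0] < len(s) and s[pos[0]] == ":":
                    pos[0] += 1
                    start = pos[0]
                    while pos[0] < len(s) and s[pos[0]] not in ",();:":
                        pos[0] += 1
                    length = float(s[start : pos[0]])
                node.children.append((child, length))
                if pos[0] < len(s) and s[pos[0]] == ",":
                    pos[0] += 1
                    continue
                break
            if pos[0] >= len(s) or s[pos[0]] != ")":
                raise ValueError("unbalanced parentheses in newick")
            pos[0] += 1
        start = pos[0]
        while pos[0] < len(s) and s[pos[0]] not in ",();:":
            pos[0] += 1
        name = s[start : pos[0]]
        if name:
            node.name = name
        return node

    root = parse_node()
    if pos[0] != len(s):
        raise ValueError(f"trailing newick content at {pos[0]}")
    return LineageTree(root=root)


@dataclass
class VariantAlignment:
    labels: list[str]
    rows: list[str]  # equal length, germline coordinates
    start: int  # germline position of column 0


def align_variants(
    labels: Sequence[str],
    seqs: Sequence[str],
    starts: Sequence[int],
    alleles: Sequence[str],
) -> VariantAlignment:
    """Project variants onto their shared germline interval.

    All variants must be annotated against the same allele; rows are truncated
    to the intersection of their covered intervals.  Gap-free and exact for
    substitution-only variants (the indel case would need a true MSA).
    """
    if len({a for a in alleles}) > 1:
        raise ValueError("variants annotated against different alleles")
    if not seqs:
        raise ValueError("no variants to align")
    start = max(starts)
    end = min(s + len(seq) for s, seq in zip(starts, seqs))
    if end < start:
        raise ValueError("variants share no covered germline interval")
    rows = [seq[start - s : end - s] for s, seq in zip(starts, seqs)]
    return VariantAlignment(labels=list(labels), rows=rows, start=start)


def pairwise_distances(
    alignment: VariantAlignment, p_distance: bool = False
) -> DistanceMatrix:
    """Hamming distance (substitution count) between every pair of rows;
    ``p_distance`` normalizes by row length."""
    rows = alignment.rows
    if len({len(r) for r in rows}) > 1:
        raise ValueError("alignment rows differ in length")
    n = len(rows)
    length = len(rows[0]) if rows else 0
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in rows]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            h = float((arrs[i] != arrs[j]).sum())
            if p_distance and length:
                h /= length
            d[i, j] = d[j, i] = h
    return DistanceMatrix(labels=list(alignment.labels), d=d)


def nj_tree(dm: DistanceMatrix) -> LineageTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Pairs minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j are joined, smallest
    (row, column) index pair first on ties.  Branch lengths follow the
    standard NJ formulas; a negative length is clamped to zero with the
    remainder moved to its sibling edge.  n < 3 degenerates to a trivial
    tree (with a warning for n == 2 handled as a single edge).
    """
    n = len(dm.labels)
    nodes = [TreeNode(name=label) for label in dm.labels]
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return LineageTree(root=nodes[0])
    if n == 2:
        root = TreeNode()
        root.children = [(nodes[0], dm.d[0, 1] / 2), (nodes[1], dm.d[0, 1] / 2)]
        return LineageTree(root=root)

    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        u = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        uid = len(nodes)
        nodes.append(u)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[uid, k] = d[k, uid] = (d[i, k] + d[j, k] - d[i, j]) / 2
        active = [k for k in active if k not in (i, j)] + [uid]

    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2
    root = TreeNode(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )
    return LineageTree(root=root)
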