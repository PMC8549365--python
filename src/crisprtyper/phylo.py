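"""Rooted neighbour joining with non-negative branch clamping.

Standard NJ agglomeration with one modification: whenever a branch length
estimate comes out negative it is set to zero and the deficit is moved onto
its sister branch, so the tip-to-tip distance of the joined pair is
preserved. The final join is resolved into a root that splits the remaining
distance equally, which is exact under the equal-branch-length assumption
the pairwise divergence estimates already make (both lineages sit at the
same distance from their common ancestor). Patristic distances are
root-position invariant, so this rooting never distorts them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidMatrix
from .oisl import DistanceMatrix

__all__ = ["TreeNode", "RootedTree", "rooted_nj", "patristic_distances"]


@dataclass
class TreeNode:
    """A node of a rooted binary tree; ``length`` is the branch above it."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class RootedTree:
    root: TreeNode

    def tips(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def tip_labels(self) -> list[str]:
        return [t.name for t in self.tips()]

    def branch_lengths(self) -> list[float]:
        out: list[float] = []

        def walk(node: TreeNode, is_root: bool) -> None:
            if not is_root:
                out.append(node.length)
            for c in node.children:
                walk(c, False)

        walk(self.root, True)
        return out

    def newick(self, digits: int = 6) -> str:
        def fmt(node: TreeNode, is_root: bool) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if is_root:
                return body
            return f"{body}:{node.length:.{digits}g}"

        return fmt(self.root, True) + ";"

    def write_newick(self, path: str | Path, digits: int = 6) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick(digits) + "\n")


def rooted_nj(d: DistanceMatrix) -> RootedTree:
    """Neighbour joining with negative branches clamped to zero.

    At each agglomeration the two branch lengths of the joined pair are the
    usual NJ estimates; a negative one is corrected to zero and the
    difference added to the adjacent (sister) branch, preserving the total
    distance between the joined pair of terminal nodes. Q-criterion ties are
    broken by the lexicographically smallest pair of clade labels, so the
    topology is deterministic.
    """
    n = len(d)
    if n < 2:
        raise InvalidMatrix("need at least two taxa")

    # active nodes: (sort key = sorted tip-label tuple, TreeNode, mean tip depth)
    nodes: list[list] = [[(lab,), TreeNode(name=lab), 0.0] for lab in d.labels]
    dist = d.values.copy()

    while len(nodes) > 2:
        m = len(nodes)
        r = dist.sum(axis=1)
        q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # ties: prefer the closest pair (keeps clock-like data balanced),
        # then the lexicographically smallest clade labels
        best = min(
            (dist[i, j], tuple(sorted((nodes[i][0], nodes[j][0]))), i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if q[i, j] <= qmin + 1e-12
        )
        _, _, i, j = best
        dij = dist[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp: move any deficit onto the sister branch; if the pair
        # distance itself is negative (possible for internal nodes of a
        # non-metric input) both branches collapse to zero
        if li < 0.0:
            li, lj = 0.0, dij
        elif lj < 0.0:
            li, lj = dij, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        ni, nj = nodes[i][1], nodes[j][1]
        ni.length, nj.length = li, lj
        parent = TreeNode(children=[ni, nj])
        key = tuple(sorted(nodes[i][0] + nodes[j][0]))
        wi, wj = len(nodes[i][0]), len(nodes[j][0])
        depth = ((nodes[i][2] + li) * wi + (nodes[j][2] + lj) * wj) / (wi + wj)

        new_row = 0.5 * (dist[i] + dist[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        dist_new = np.zeros((len(keep) + 1, len(keep) + 1))
        dist_new[:-1, :-1] = dist[np.ix_(keep, keep)]
        dist_new[-1, :-1] = dist_new[:-1, -1] = new_row[keep]
        nodes = [nodes[k] for k in keep] + [[key, parent, depth]]
        dist = dist_new

    # root on the final edge at the depth-balancing point, so the two sides
    # end up with equal mean tip depth (the equal split of the 2-taxon case);
    # patristic distances are invariant to the root position on this edge
    (_, na, da), (_, nb, db) = nodes
    dab = dist[0, 1]
    xa = min(max((dab + db - da) / 2.0, 0.0), dab)
    na.length, nb.length = xa, dab - xa
    return RootedTree(root=TreeNode(children=[na, nb]))


def patristic_distances(tree: RootedTree) -> DistanceMatrix:
    """Tip-to-tip path-length distances (sum of branch lengths)."""
    labels: list[str] = []
    n_tips = len(tree.tips())
    dmat = np.zeros((n_tips, n_tips))
    index: dict[str, int] = {}

    def walk(node: TreeNode) -> dict[int, float]:
        """Map tip index -> distance from ``node``; fills cross-pair cells."""
        if node.is_leaf:
            index[node.name] = len(labels)
            labels.append(node.name)
            return {index[node.name]: 0.0}
        below: list[dict[int, float]] = []
        for child in node.children:
            sub = walk(child)
            below.append({t: dd + child.length for t, dd in sub.items()})
        for a in range(len(below)):
            for b in range(a + 1, len(below)):
                for ti, di in below[a].items():
                    for tj, dj in below[b].items():
                        dmat[ti, tj] = dmat[tj, ti] = di + dj
        return {t: dd for sub in below for t, dd in sub.items()}

    walk(tree.root)
    return DistanceMatrix(labels, dmat)


def read_newick(path: str | Path) -> RootedTree:
    """Parse a Newick file written by :meth:`RootedTree.write_newick`."""
    text = Path(path).read_text().strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def parse() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            node.children.append(parse())
            while s[pos] == ",":
                pos += 1
                node.children.append(parse())
            if s[pos] != ")":
                raise ValueError(f"expected ')' at {pos}")
            pos += 1
        start = pos
        while pos < len(s) and s[pos] not in ":,()":
            pos += 1
        name = s[start:pos]
        if name:
            node.name = name
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse()
    if pos != len(s):
        raise ValueError("trailing characters in newick string")
    if any(not math.isfinite(x) or x < 0 for x in RootedTree(root).branch_lengths()):
        raise ValueError("negative or non-finite branch length")
    return RootedTree(root=root)
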