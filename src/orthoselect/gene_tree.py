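"""Per-cluster gene trees: neighbor joining, Newick/Nexus interop, foreground marks.

Trees here are unrooted (represented with a trifurcating "root" node);
branch lengths are on the expected-substitutions scale and serve as starting
values for the likelihood optimizer, which re-estimates them under every
model. A single terminal branch may carry a foreground mark, emitted with
the " #1" convention so branch/branch-site model files remain compatible
with PAML-style tooling.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class TreeNode:
    name: str | None = None            # leaf label; None for internal nodes
    length: float = 0.0                # branch length to parent (root: unused)
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class GeneTree:
    """Unrooted gene tree over one cluster's species."""

    root: TreeNode
    foreground: str | None = None

    # -- basic structure -------------------------------------------------
    def leaves(self) -> list[str]:
        out: list[str] = []
        def walk(n: TreeNode) -> None:
            if n.is_leaf:
                out.append(n.name)
            for c in n.children:
                walk(c)
        walk(self.root)
        return out

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        def walk(n: TreeNode) -> None:
            for c in n.children:
                walk(c)
            out.append(n)
        walk(self.root)
        return out

    def n_edges(self) -> int:
        return len(self.postorder()) - 1

    def branch_lengths(self) -> np.ndarray:
        return np.array([n.length for n in self.postorder()[:-1]], dtype=float)

    def set_branch_lengths(self, lengths: np.ndarray) -> None:
        nodes = self.postorder()[:-1]
        if len(lengths) != len(nodes):
            raise ValueError("branch length vector does not match edge count")
        for n, t in zip(nodes, lengths):
            n.length = float(t)

    def with_foreground(self, leaf: str) -> "GeneTree":
        if leaf not in self.leaves():
            raise ValueError(f"foreground taxon {leaf!r} is not a leaf of the tree")
        return GeneTree(root=self.root, foreground=leaf)

    # -- comparisons ------------------------------------------------------
    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-side leaf set."""
        all_leaves = frozenset(self.leaves())
        out: set[frozenset[str]] = set()
        def walk(n: TreeNode) -> frozenset[str]:
            if n.is_leaf:
                return frozenset([n.name])
            below = frozenset().union(*(walk(c) for c in n.children))
            if n is not self.root and 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(below if tuple(sorted(below)) < tuple(sorted(other)) else other)
            return below
        walk(self.root)
        return out

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distance matrix between leaves."""
        names = sorted(self.leaves())
        idx = {n: i for i, n in enumerate(names)}
        dist = np.zeros((len(names), len(names)))
        def walk(n: TreeNode) -> dict[str, float]:
            if n.is_leaf:
                return {n.name: 0.0}
            sub = [walk(c) for c in n.children]
            for k, c in enumerate(sub):
                for name in c:
                    c[name] += n.children[k].length
            for a in range(len(sub)):
                for b in range(a + 1, len(sub)):
                    for na, da in sub[a].items():
                        for nb, db in sub[b].items():
                            dist[idx[na], idx[nb]] = dist[idx[nb], idx[na]] = da + db
            merged: dict[str, float] = {}
            for c in sub:
                merged.update(c)
            return merged
        walk(self.root)
        return names, dist


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

MAX_PROTEIN_DISTANCE = 5.0


def pairwise_distances(taxa: list[str], rows: list[str]) -> np.ndarray:
    """Kimura-corrected protein distances over shared ungapped columns.

    p is the mismatch fraction over columns where both rows have residues;
    d = -ln(1 - p - 0.2 p^2), capped at MAX_PROTEIN_DISTANCE once the
    correction diverges (p >= 0.85).
    """
    n = len(taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    arr = np.array([list(r) for r in rows])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (arr[i] != "-") & (arr[j] != "-")
            m = int(shared.sum())
            if m == 0:
                raise ValueError(
                    f"no shared ungapped columns between {taxa[i]} and {taxa[j]}")
            p = float((arr[i][shared] != arr[j][shared]).mean())
            if p >= 0.85:
                d = MAX_PROTEIN_DISTANCE
            else:
                d = -math.log(1.0 - p - 0.2 * p * p)
            dist[i, j] = dist[j, i] = d
    return dist


def nj_tree(distances: np.ndarray, labels: list[str]) -> GeneTree:
    """Saitou–Nei neighbor joining with deterministic lowest-index tie-breaks.

    Negative branch-length estimates are clamped to 0. On an additive matrix
    the generating tree (topology and lengths) is recovered exactly.
    """
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T) or not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be symmetric and finite")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    active = list(range(n))
    D = D.copy()

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-(i,j) tie break in the active-index ordering
        best = np.unravel_index(np.argmin(Q), Q.shape)
        a, b = sorted(best)
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (R[a] - R[b]) / (2 * (r - 2))
        lj = dij - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes.append(parent)
        new = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d = 0.5 * (D[i, k] + D[j, k] - dij)
            D[new, k] = D[k, new] = d
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return GeneTree(root=root)


# ---------------------------------------------------------------------------
# Newick ("dnd") and Nexus
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def to_newick(tree: GeneTree, labeled: bool = False) -> str:
    """Emit Newick with 6-significant-digit branch lengths.

    With ``labeled=True`` and a foreground set, the foreground terminal
    branch carries the " #1" mark (PAML convention).
    """
    def emit(n: TreeNode, at_root: bool) -> str:
        if n.is_leaf:
            s = f"{n.name}:{_fmt(n.length)}"
            if labeled and tree.foreground == n.name:
                s += " #1"
            return s
        inner = ",".join(emit(c, False) for c in n.children)
        if at_root:
            return f"({inner})"
        return f"({inner}):{_fmt(n.length)}"
    return emit(tree.root, True) + ";"


def parse_newick(text: str) -> GeneTree:
    """Parse Newick, accepting PAML-style " #1" foreground marks on leaves."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0
    foreground: list[str] = []

    def error(msg: str) -> ValueError:
        return ValueError(f"malformed Newick at position {pos}: {msg}")

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise error("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected {s[pos]!r}")
        # name
        start = pos
        while pos < len(s) and s[pos] not in ":,()#;":
            pos += 1
        name = s[start:pos].strip()
        if name:
            node.name = name
        # branch length
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()# ":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                raise error(f"bad branch length {s[start:pos]!r}")
        # optional " #1" mark
        while pos < len(s) and s[pos] == " ":
            pos += 1
        if pos < len(s) and s[pos] == "#":
            pos += 1
            start = pos
            while pos < len(s) and s[pos].isdigit():
                pos += 1
            if node.name is None or not node.is_leaf:
                raise error("branch marks are only supported on terminal branches")
            foreground.append(node.name)
        return node

    root = parse_node()
    if pos != len(s):
        raise error("trailing characters")
    if len(foreground) > 1:
        raise ValueError("more than one foreground mark in tree")
    if root.is_leaf:
        raise ValueError("tree has no internal structure")
    return GeneTree(root=root, foreground=foreground[0] if foreground else None)


def emit_nexus(tree: GeneTree, tree_name: str = "gene") -> str:
    """Nexus TREES block with a translate table (taxa numbered in leaf order)."""
    leaves = tree.leaves()
    number = {name: i + 1 for i, name in enumerate(leaves)}
    def emit(n: TreeNode, at_root: bool) -> str:
        if n.is_leaf:
            return f"{number[n.name]}:{_fmt(n.length)}"
        inner = ",".join(emit(c, False) for c in n.children)
        return f"({inner})" if at_root else f"({inner}):{_fmt(n.length)}"
    lines = ["#NEXUS", "begin trees;", "    translate"]
    for i, name in enumerate(leaves):
        sep = "," if i < len(leaves) - 1 else ""
        lines.append(f"        {number[name]} {name}{sep}")
    lines.append("    ;")
    lines.append(f"    tree {tree_name} = [&U] {emit(tree.root, True)};")
    lines.append("end;")
    return "\n".join(lines) + "\n"


def parse_nexus(text: str) -> GeneTree:
    """Parse a Nexus TREES block (translate tables supported) via dendropy."""
    dtree = dendropy.Tree.get(data=text, schema="nexus", preserve_underscores=True)
    newick = dtree.as_string(schema="newick", unquoted_underscores=True,
                             suppress_rooting=True).strip()
    return parse_newick(newick)


def nexus_to_dnd(text: str) -> str:
    """Convert a Nexus tree file to plain Newick (the pipeline's "dnd" format)."""
    return to_newick(parse_nexus(text))


def prune_to_taxa(newick: str, taxa: list[str]) -> GeneTree:
    """Prune a (species) tree down to the given taxa, keeping branch lengths.

    Raises ValueError naming any requested taxon absent from the tree.
    """
    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
    have = {t.label for t in dtree.taxon_namespace}
    missing = sorted(set(taxa) - have)
    if missing:
        raise ValueError(f"species tree is missing taxa: {missing}")
    dtree.retain_taxa_with_labels(taxa)
    out = dtree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True).strip()
    tree = parse_newick(out)
    return unroot(tree)


def unroot(tree: GeneTree) -> GeneTree:
    """Collapse a bifurcating root into the trifurcating unrooted form.

    Operates on a copy; the input tree is left untouched.
    """
    import copy

    root = copy.deepcopy(tree.root)
    while len(root.children) == 2 and len(tree.leaves()) >= 3:
        a, b = root.children
        donor = a if not a.is_leaf else b
        other = b if donor is a else a
        other.length += donor.length
        root = TreeNode(children=donor.children + [other])
    return GeneTree(root=root, foreground=tree.foreground)
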