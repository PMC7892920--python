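"""Rooted phylogenetic trees: newick I/O, random guide trees, scaling, and tree metrics.

The tree type is deliberately small: named leaves, stable internal-node
identifiers (needed by the gain/loss and phylostratigraphy bookkeeping),
branch lengths in expected substitutions per site. Newick parsing is
delegated to dendropy and the result converted into this structure.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "Node",
    "PhyloTree",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "generate_guide_tree",
    "scale_tree",
    "patristic_distance",
    "patristic_matrix",
    "mrca",
    "bipartitions",
    "rf_distance",
]


class NewickParseError(ValueError):
    """Raised for malformed newick input (message names the offending token/position)."""


class Node:
    """One tree node. Leaves have a ``name``; every node gets a stable ``id``."""

    __slots__ = ("name", "length", "parent", "children", "id")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.id: str = ""

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.id or self.name}>"


class PhyloTree:
    """Rooted tree with named leaves and stable internal-node ids.

    Invariants enforced at construction: exactly one root, unique leaf
    labels, finite non-negative branch lengths.
    """

    def __init__(self, root: Node):
        self.root = root
        self.root.parent = None
        self.root.length = 0.0
        self._assign_ids()
        self._leaf_map = {leaf.name: leaf for leaf in self.leaves()}
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None or n == "" for n in names):
            raise ValueError("all leaves must be labelled")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NewickParseError(f"duplicate leaf labels: {dup}")
        for node in self.iter_nodes():
            if not np.isfinite(node.length) or node.length < 0:
                raise ValueError(f"branch length of {node.id!r} must be finite and >= 0")

    def _assign_ids(self) -> None:
        k = 0
        for node in self.iter_nodes():
            if node.is_leaf:
                node.id = node.name or ""
            else:
                node.id = f"n{k}"
                k += 1

    # -- traversal ---------------------------------------------------------
    def iter_nodes(self) -> Iterator[Node]:
        """Preorder traversal (root first)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_map)

    def leaf(self, name: str) -> Node:
        try:
            return self._leaf_map[name]
        except KeyError:
            raise KeyError(f"unknown leaf label: {name!r}") from None

    def node_by_id(self, node_id: str) -> Node:
        for node in self.iter_nodes():
            if node.id == node_id:
                return node
        raise KeyError(f"unknown node id: {node_id!r}")

    def leafset_below(self, node: Node) -> frozenset[str]:
        """Set of leaf labels subtended by ``node``."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def depths(self) -> dict[str, float]:
        """Root-to-node path length for every node, keyed by node id."""
        d: dict[str, float] = {}
        for node in self.iter_nodes():
            d[node.id] = node.length + (d[node.parent.id] if node.parent else 0.0)
        return d

    # -- structural helpers -------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            c = Node(node.name, node.length)
            for ch in node.children:
                c.add_child(clone(ch))
            return c

        return PhyloTree(clone(self.root))

    def is_bifurcating(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.iter_nodes())

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_leaves} leaves>"


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a single newick statement (must end with ';') into a :class:`PhyloTree`.

    Dialect: branch lengths after colons, optional internal labels (kept as
    node names but ignored by the metrics), no quoted labels / NHX.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"missing ';' terminator at position {len(text.rstrip())}"
        )
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types with positions
        raise NewickParseError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> Node:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        node = Node(name=name, length=dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    # internal labels are cosmetic; drop them so ids stay canonical
    for node in _preorder(root):
        if node.children:
            node.name = None
    return PhyloTree(root)


def _preorder(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def write_newick(tree: PhyloTree) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.parent is None:
            return body
        return f"{body}:{node.length:.10g}"

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# generation and scaling
# ---------------------------------------------------------------------------

def _default_branch_law(rng: np.random.Generator, size: int) -> np.ndarray:
    # log-normal, median 0.05, sigma such that ~95% of draws lie in [0.005, 0.5]
    sigma = np.log(10.0) / 1.959964
    return rng.lognormal(mean=np.log(0.05), sigma=sigma, size=size)


def generate_guide_tree(
    n_leaves: int,
    seed: int,
    branch_length_law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> PhyloTree:
    """Random rooted bifurcating tree with heterogeneous branch lengths.

    Topology is grown by sequential random attachment (each new leaf splits
    a uniformly chosen existing branch), which is uniform over labelled
    topologies; branch lengths are then drawn i.i.d. from
    ``branch_length_law`` (default log-normal with median 0.05 and ~95% of
    mass in [0.005, 0.5]). Deterministic for a fixed seed.
    """
    if n_leaves < 3:
        raise ValueError(f"n_leaves must be >= 3, got {n_leaves}")
    rng = np.random.default_rng(seed)
    law = branch_length_law or _default_branch_law

    width = len(str(n_leaves))
    names = [f"sp{str(i + 1).zfill(width)}" for i in range(n_leaves)]

    root = Node()
    root.add_child(Node(names[0]))
    root.add_child(Node(names[1]))
    attachable: list[Node] = list(root.children)  # every non-root node owns its edge

    for name in names[2:]:
        target = attachable[int(rng.integers(len(attachable)))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        leaf = Node(name)
        mid.add_child(leaf)
        attachable.extend([mid, leaf])

    lengths = np.asarray(law(rng, len(attachable)), dtype=float)
    if np.any(lengths <= 0) or not np.all(np.isfinite(lengths)):
        raise ValueError("branch_length_law must return positive finite lengths")
    for node, ln in zip(attachable, lengths):
        node.length = float(ln)
    return PhyloTree(root)


def scale_tree(tree: PhyloTree, multiplier: float) -> PhyloTree:
    """Return a copy with every branch length multiplied by ``multiplier`` (> 0)."""
    if not np.isfinite(multiplier) or multiplier <= 0:
        raise ValueError(f"multiplier must be > 0, got {multiplier}")
    out = tree.copy()
    for node in out.iter_nodes():
        if node.parent is not None:
            node.length *= multiplier
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _path_to_root(node: Node) -> list[Node]:
    path = []
    while node is not None:
        path.append(node)
        node = node.parent
    return path


def mrca(tree: PhyloTree, leaves: Iterable[str]) -> Node:
    """Most recent common ancestor of a non-empty set of leaf labels."""
    labels = list(leaves)
    if not labels:
        raise ValueError("mrca of an empty leaf set is undefined")
    paths = []
    for lab in labels:
        paths.append(_path_to_root(tree.leaf(lab)))
    common = set(id(n) for n in paths[0])
    for p in paths[1:]:
        common &= set(id(n) for n in p)
    # deepest common node = first element of any path that is common
    for node in paths[0]:
        if id(node) in common:
            return node
    raise AssertionError("trees are connected; unreachable")  # pragma: no cover


def patristic_distance(tree: PhyloTree, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    a, b = tree.leaf(leaf_a), tree.leaf(leaf_b)
    if a is b:
        return 0.0
    anc = mrca(tree, [leaf_a, leaf_b])
    d = 0.0
    for node in (a, b):
        while node is not anc:
            d += node.length
            node = node.parent
    return d


def patristic_matrix(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """All-pairs patristic distances; returns (sorted labels, dense matrix)."""
    labels = sorted(tree.leaf_names)
    depths = tree.depths()
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            anc = mrca(tree, [labels[i], labels[j]])
            d = depths[labels[i]] + depths[labels[j]] - 2.0 * depths[anc.id]
            mat[i, j] = mat[j, i] = d
    return labels, mat


def bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each encoded as the block not
    containing the lexicographically smallest leaf label."""
    all_leaves = frozenset(tree.leaf_names)
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.iter_nodes():
        if node.parent is None:
            continue
        below = tree.leafset_below(node)
        side = below if ref not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def rf_distance(tree_a: PhyloTree, tree_b: PhyloTree) -> int:
    """Robinson-Foulds distance: symmetric difference of non-trivial unrooted splits."""
    la, lb = set(tree_a.leaf_names), set(tree_b.leaf_names)
    if la != lb:
        raise ValueError("trees must share an identical leaf-label set")
    return len(bipartitions(tree_a) ^ bipartitions(tree_b))
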