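"""Species-tree reconstruction from the presence/absence matrix.

Jaccard dissimilarity over orthogroup membership followed by
neighbor-joining. This is a deterministic, desk-fast stand-in for
binary-character ML tree search; the matrix can also be exported in relaxed
PHYLIP binary form for external ML programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pa_matrix import PresenceAbsenceMatrix
from .trees import Node, PhyloTree, bipartitions, rf_distance

__all__ = ["DistanceMatrix", "pa_distance", "nj_tree", "score_against_guide", "star_rf"]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    @property
    def is_degenerate(self) -> bool:
        """True when the off-diagonal entries carry no signal (all equal)."""
        off = self.values[~np.eye(len(self.labels), dtype=bool)]
        return bool(np.ptp(off) < 1e-12)


def pa_distance(matrix: PresenceAbsenceMatrix) -> DistanceMatrix:
    """Jaccard dissimilarity between species over orthogroup membership:
    d(a,b) = 1 - shared(a,b) / (n_a + n_b - shared(a,b))."""
    if len(matrix.species) < 3:
        raise ValueError("need >= 3 species")
    zero = matrix.row_sums[matrix.row_sums == 0]
    if len(zero):
        raise ValueError(f"species with zero presences: {list(zero.index)}")
    m = matrix.frame.to_numpy().astype(np.int64)
    shared = m @ m.T
    rows = m.sum(axis=1)
    union = rows[:, None] + rows[None, :] - shared
    d = 1.0 - shared / union
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(matrix.species), values=d)


def nj_tree(dist: DistanceMatrix) -> tuple[PhyloTree, int]:
    """Neighbor joining with the standard Q criterion.

    Deterministic: ties in the Q minimum are broken lexicographically by the
    pair's (smallest-leaf-below) labels. Negative branch-length estimates
    are clamped to 0; the number of clamps is returned alongside the tree.
    The returned tree is rooted (arbitrarily) at the final join, which has
    three children — downstream RF comparison is unrooted.
    """
    labels = list(dist.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    d = dist.values.copy()
    nodes: list[Node] = [Node(name=lab) for lab in labels]
    # tie-break key: the lexicographically smallest leaf below each working node
    keys: list[str] = list(labels)
    active = list(range(n))
    clamped = 0

    def set_length(node: Node, value: float) -> None:
        nonlocal clamped
        if value < 0:
            clamped += 1
            value = 0.0
        node.length = float(value)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            (min(keys[active[i]], keys[active[j]]), max(keys[active[i]], keys[active[j]]), i, j)
            for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12)))
            if i < j
        ]
        _, _, i, j = min(candidates)
        a, b = active[i], active[j]
        dij = d[a, b]
        la = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lb = dij - la
        parent = Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        set_length(nodes[a], la)
        set_length(nodes[b], lb)
        # distances to the new node
        new_row = 0.5 * (d[a, :] + d[b, :] - dij)
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        nodes.append(parent)
        keys.append(min(keys[a], keys[b]))
        active = [x for x in active if x not in (a, b)] + [len(nodes) - 1]

    a, b, c = active
    root = Node()
    for x in (a, b, c):
        root.add_child(nodes[x])
    set_length(nodes[a], 0.5 * (d[a, b] + d[a, c] - d[b, c]))
    set_length(nodes[b], 0.5 * (d[a, b] + d[b, c] - d[a, c]))
    set_length(nodes[c], 0.5 * (d[a, c] + d[b, c] - d[a, b]))
    return PhyloTree(root), clamped


def star_rf(guide: PhyloTree) -> int:
    """RF of a completely unresolved (star) reconstruction against the guide."""
    return len(bipartitions(guide))


def max_rf(guide: PhyloTree) -> int:
    """Largest possible RF against the guide: a fully resolved tree sharing no
    splits. This is the score a no-signal replicate is assigned (flagged):
    forcing a tree through a signal-free matrix yields an effectively random
    resolved topology, which lands at this ceiling."""
    return 2 * len(bipartitions(guide))


def score_against_guide(reconstructed: PhyloTree, guide: PhyloTree) -> int:
    """Unrooted Robinson-Foulds distance to the guide tree."""
    return rf_distance(reconstructed, guide)
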