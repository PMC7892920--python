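"""Dollo-parsimony gain/loss mapping on the rooted guide tree.

Each orthogroup is gained exactly once — at the MRCA of the species that
carry it — and may be lost any number of times afterwards. The minimum-loss
scenario under this single-gain constraint is unique: one loss on the
branch to every maximal all-absent subtree inside the gain clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pa_matrix import PresenceAbsenceMatrix
from .trees import Node, PhyloTree, mrca

__all__ = ["GainLossMap", "dollo_map_one", "dollo_map_all", "compare_maps"]


@dataclass
class GainLossMap:
    """Per-node gain counts and per-branch loss counts (keyed by the node the
    branch subtends), plus totals. Total gains always equal the number of
    orthogroups mapped (the Dollo invariant)."""

    tree: PhyloTree
    gains: dict[str, int]
    losses: dict[str, int]

    @property
    def total_gains(self) -> int:
        return int(sum(self.gains.values()))

    @property
    def total_losses(self) -> int:
        return int(sum(self.losses.values()))

    def as_frame(self) -> pd.DataFrame:
        ids = [n.id for n in self.tree.iter_nodes()]
        return pd.DataFrame(
            {
                "node": ids,
                "gains": [self.gains.get(i, 0) for i in ids],
                "losses": [self.losses.get(i, 0) for i in ids],
            }
        )

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False)


def dollo_map_one(tree: PhyloTree, present_leaves: frozenset[str] | set[str]) -> tuple[Node, list[Node]]:
    """Minimum-loss single-gain scenario for one presence pattern.

    Returns the gain node (MRCA of the present leaves) and the list of nodes
    whose subtending branches carry a loss (roots of the maximal all-absent
    subtrees within the gain clade).
    """
    present = set(present_leaves)
    if not present:
        raise ValueError("presence set is empty")
    unknown = present - set(tree.leaf_names)
    if unknown:
        raise ValueError(f"unknown leaves in presence set: {sorted(unknown)}")
    gain = mrca(tree, present)

    losses: list[Node] = []

    def any_present(node: Node) -> bool:
        if node.is_leaf:
            return node.name in present
        return any(any_present(c) for c in node.children)

    def walk(node: Node) -> None:
        for child in node.children:
            if any_present(child):
                walk(child)
            else:
                losses.append(child)

    walk(gain)
    return gain, losses


def dollo_map_all(tree: PhyloTree, matrix: PresenceAbsenceMatrix) -> GainLossMap:
    """Aggregate Dollo scenarios over every orthogroup column of the matrix."""
    unknown = set(matrix.species) - set(tree.leaf_names)
    if unknown:
        raise ValueError(f"matrix species not on tree: {sorted(unknown)}")
    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    # distinct presence patterns are mapped once and weighted by multiplicity
    patterns: dict[frozenset[str], int] = {}
    for col in matrix.frame.columns:
        pat = matrix.presence_set(col)
        patterns[pat] = patterns.get(pat, 0) + 1
    for pat, count in patterns.items():
        gain, loss_nodes = dollo_map_one(tree, pat)
        gains[gain.id] = gains.get(gain.id, 0) + count
        for node in loss_nodes:
            losses[node.id] = losses.get(node.id, 0) + count
    return GainLossMap(tree=tree, gains=gains, losses=losses)


@dataclass(frozen=True)
class MapComparison:
    table: pd.DataFrame
    rho_gains: float
    rho_losses: float


def compare_maps(map_a: GainLossMap, map_b: GainLossMap) -> MapComparison:
    """Align two gain/loss maps node-by-node and compute Spearman rank
    correlations (midrank ties) for gains and for losses."""
    ids_a = [n.id for n in map_a.tree.iter_nodes()]
    ids_b = [n.id for n in map_b.tree.iter_nodes()]
    if ids_a != ids_b:
        raise ValueError("gain/loss maps are on different trees")
    table = pd.DataFrame(
        {
            "node": ids_a,
            "gains_a": [map_a.gains.get(i, 0) for i in ids_a],
            "gains_b": [map_b.gains.get(i, 0) for i in ids_a],
            "losses_a": [map_a.losses.get(i, 0) for i in ids_a],
            "losses_b": [map_b.losses.get(i, 0) for i in ids_a],
        }
    )
    rho_g = stats.spearmanr(table["gains_a"], table["gains_b"]).statistic
    rho_l = stats.spearmanr(table["losses_a"], table["losses_b"]).statistic
    return MapComparison(table=table, rho_gains=float(rho_g), rho_losses=float(rho_l))


def annotate_newick(map_: GainLossMap) -> str:
    """Newick with per-node gain/loss annotations as comments."""
    def fmt(node: Node) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        note = f"[g={map_.gains.get(node.id, 0)},l={map_.losses.get(node.id, 0)}]"
        if node.parent is None:
            return body + note
        return f"{body}{note}:{node.length:.10g}"

    return fmt(map_.tree.root) + ";"
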