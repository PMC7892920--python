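"""Phylostratigraphy: gene-age ranks for a focal species and the replicate
Average Gene Age (AGA).

Strata are the nodes on the root-to-focal-leaf path: rank 1 is the root
(oldest), rank D the focal terminal branch (youngest). A focal gene's age
is the rank of the smallest stratum whose leaf set still contains every
species in its orthogroup — i.e. the path position of the MRCA of the
orthogroup's species together with the focal leaf. Since all simulated
families are present everywhere, any AGA above 1 is pure inference
artifact: fast-evolving genes appear younger than they are.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .engine import OrthogroupSet
from .simulate import parse_gene_id
from .trees import PhyloTree

__all__ = ["StrataDefinition", "AgeAssignment", "define_strata", "assign_age", "average_gene_age"]


@dataclass(frozen=True)
class StrataDefinition:
    """Ordered strata on the root-to-focal path; leaf sets strictly nested."""

    focal: str
    node_ids: tuple[str, ...]            # rank r corresponds to node_ids[r-1]
    leaf_sets: tuple[frozenset[str], ...]

    @property
    def depth(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True)
class AgeAssignment:
    ranks: dict[str, int]  # focal gene id -> age rank
    aga: float             # mean rank over all focal genes

    def as_frame(self, strata: StrataDefinition) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.ranks),
                "rank": list(self.ranks.values()),
                "stratum_node": [strata.node_ids[r - 1] for r in self.ranks.values()],
            }
        )


def define_strata(tree: PhyloTree, focal: str) -> StrataDefinition:
    """Enumerate the root-to-focal path with rank 1 at the root."""
    node = tree.leaf(focal)  # raises KeyError for unknown labels
    path = []
    while node is not None:
        path.append(node)
        node = node.parent
    path.reverse()
    leaf_sets = tuple(tree.leafset_below(n) for n in path)
    return StrataDefinition(
        focal=focal, node_ids=tuple(n.id for n in path), leaf_sets=leaf_sets
    )


def assign_age(member_species: frozenset[str] | set[str], strata: StrataDefinition) -> int:
    """Rank of the smallest stratum containing every species of the orthogroup."""
    members = set(member_species)
    if strata.focal not in members:
        raise ValueError("orthogroup does not contain the focal species")
    rank = 1  # root stratum contains everything
    for r in range(2, strata.depth + 1):
        if members <= strata.leaf_sets[r - 1]:
            rank = r
        else:
            break  # leaf sets are nested; once too small, all deeper ones are too
    return rank


def average_gene_age(
    orthogroups: OrthogroupSet, strata: StrataDefinition, focal: str
) -> AgeAssignment:
    """Assign an age rank to every focal-species gene and average them.

    A focal gene in a singleton cluster has member set {focal}, which only
    the terminal stratum contains — it is called lineage-specific (rank D).
    """
    ranks: dict[str, int] = {}
    for cluster, spset in zip(orthogroups.clusters, orthogroups.species_sets()):
        if focal not in spset:
            continue
        rank = assign_age(spset, strata)
        for gid in cluster:
            if parse_gene_id(gid)[0] == focal:
                ranks[gid] = rank
    if not ranks:
        raise ValueError(f"focal species {focal!r} has no genes")
    return AgeAssignment(ranks=ranks, aga=float(sum(ranks.values()) / len(ranks)))
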