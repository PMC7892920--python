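"""Species x orthogroup presence/absence matrix and its summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import OrthogroupSet
from .simulate import GeneFamilyAlignment, parse_gene_id
from .trees import PhyloTree

__all__ = [
    "PresenceAbsenceMatrix",
    "build_matrix",
    "summarize",
    "shared_orthogroups",
    "orthogroup_rate_vs_span",
]


class PresenceAbsenceMatrix:
    """Binary species x orthogroup matrix (1 = the species has >= 1 member).

    Backed by a pandas DataFrame with species as rows and orthogroup ids as
    columns; every column has at least one presence by construction.
    """

    def __init__(self, frame: pd.DataFrame):
        values = frame.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        if (values.sum(axis=0) == 0).any():
            raise ValueError("every orthogroup column must have >= 1 presence")
        self.frame = frame.astype(np.int8)
        self.row_sums = self.frame.sum(axis=1)
        self.col_sums = self.frame.sum(axis=0)

    @property
    def species(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n_orthogroups(self) -> int:
        return self.frame.shape[1]

    def presence_set(self, column) -> frozenset[str]:
        col = self.frame[column]
        return frozenset(col.index[col == 1])

    def shared_matrix(self) -> pd.DataFrame:
        """Pairwise counts of orthogroups present in both species."""
        m = self.frame.to_numpy()
        return pd.DataFrame(m @ m.T, index=self.frame.index, columns=self.frame.index)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="species")

    def to_phylip(self, path) -> None:
        """Relaxed PHYLIP binary: counts line, then 'species 0/1-string' rows."""
        with open(path, "w") as fh:
            fh.write(f"{self.frame.shape[0]} {self.frame.shape[1]}\n")
            for sp, row in self.frame.iterrows():
                fh.write(f"{sp}  {''.join(map(str, row.to_numpy()))}\n")


def build_matrix(orthogroups: OrthogroupSet, species: list[str]) -> PresenceAbsenceMatrix:
    """Binary matrix over ``species`` with one column per orthogroup."""
    data = np.zeros((len(species), orthogroups.n_orthogroups), dtype=np.int8)
    sp_index = {s: i for i, s in enumerate(species)}
    for ci, cluster in enumerate(orthogroups.clusters):
        for gid in cluster:
            sp = parse_gene_id(gid)[0]
            if sp not in sp_index:
                raise ValueError(f"orthogroup member from unknown species: {sp!r}")
            data[sp_index[sp], ci] = 1
    cols = [f"OG{ci:07d}" for ci in range(orthogroups.n_orthogroups)]
    return PresenceAbsenceMatrix(pd.DataFrame(data, index=list(species), columns=cols))


@dataclass(frozen=True)
class MatrixSummary:
    n_orthogroups: int
    mean_size_genes: float
    mean_species_per_orthogroup: float
    frac_singletons: float


def summarize(matrix: PresenceAbsenceMatrix, orthogroups: OrthogroupSet) -> MatrixSummary:
    sizes = orthogroups.sizes
    return MatrixSummary(
        n_orthogroups=orthogroups.n_orthogroups,
        mean_size_genes=float(sizes.mean()),
        mean_species_per_orthogroup=float(matrix.col_sums.mean()),
        frac_singletons=float((sizes == 1).mean()),
    )


def shared_orthogroups(matrix: PresenceAbsenceMatrix, species_a: str, species_b: str) -> int:
    """Number of orthogroups present in both species."""
    for sp in (species_a, species_b):
        if sp not in matrix.frame.index:
            raise KeyError(f"unknown species: {sp!r}")
    a = matrix.frame.loc[species_a].to_numpy()
    b = matrix.frame.loc[species_b].to_numpy()
    return int((a & b).sum())


def orthogroup_rate_vs_span(
    orthogroups: OrthogroupSet,
    families: list[GeneFamilyAlignment],
    tree: PhyloTree,
    species_pair: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-orthogroup (divergence between the pair's members, species count).

    For each orthogroup containing both species of the pair, the observed
    sequence divergence between the pair's members (p-distance, a relative
    rate) is paired with the number of species represented in the
    orthogroup. Returns (divergences, species_counts, degenerate) where
    ``degenerate`` flags a constant species-count vector (correlation
    undefined, e.g. perfect inference).
    """
    sp_a, sp_b = species_pair
    seq_lookup: dict[str, np.ndarray] = {}
    for fam in families:
        for sp, seq in fam.sequences.items():
            seq_lookup[f"{sp}|{fam.family_id}"] = seq

    divergences, counts = [], []
    for cluster, spset in zip(orthogroups.clusters, orthogroups.species_sets()):
        if sp_a not in spset or sp_b not in spset:
            continue
        ga = min(g for g in cluster if parse_gene_id(g)[0] == sp_a)
        gb = min(g for g in cluster if parse_gene_id(g)[0] == sp_b)
        sa, sb = seq_lookup[ga], seq_lookup[gb]
        if len(sa) != len(sb):  # cross-family merge; fall back to shorter prefix
            m = min(len(sa), len(sb))
            sa, sb = sa[:m], sb[:m]
        divergences.append(float(np.mean(sa != sb)))
        counts.append(len(spset))
    if not divergences:
        raise ValueError(f"species pair {species_pair} co-occurs in no orthogroup")
    div = np.asarray(divergences)
    cnt = np.asarray(counts, dtype=float)
    degenerate = bool(np.ptp(cnt) == 0)
    return div, cnt, degenerate
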