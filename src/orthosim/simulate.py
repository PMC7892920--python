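"""Amino-acid sequence simulation along a tree.

Continuous-time reversible Markov substitution at every site, with
continuous gamma among-site rate variation (shape alpha, mean 1). Families
evolve independently along the guide tree pre-scaled by the replicate's
gene-rate multiplier; there are no indels, duplications, gains or losses,
so the true orthology of every simulated gene is known by construction.

Two substitution presets:

* ``poisson`` — equal exchangeabilities, uniform frequencies; admits the
  20-state analogue of the Jukes-Cantor closed form used in tests.
* ``blosum62`` — a general reversible matrix whose exchangeabilities are
  read off the BLOSUM62 half-bit log-odds table, r_ij = 2^(B_ij/2), with
  stationary frequencies recovered from the log-odds consistency relation
  sum_j f_j 2^(B_ij/2) = 1. This is the default for the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import ReplicateParams
from .trees import Node, PhyloTree, scale_tree

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"  # canonical 20-letter order
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

__all__ = [
    "AMINO_ACIDS",
    "SubstitutionModel",
    "GeneFamilyAlignment",
    "draw_site_rates",
    "evolve_branch",
    "simulate_family",
    "simulate_replicate",
    "write_proteomes",
    "read_proteomes",
    "seq_to_str",
    "str_to_seq",
]


def seq_to_str(seq: np.ndarray) -> str:
    return _AA_ARRAY[np.asarray(seq, dtype=np.intp)].tobytes().decode()


def str_to_seq(s: str) -> np.ndarray:
    return np.array([AA_INDEX[c] for c in s], dtype=np.int8)


class SubstitutionModel:
    """Time-reversible 20-state substitution model.

    Built from a symmetric exchangeability matrix and stationary
    frequencies; the rate matrix is normalized so the expected number of
    substitutions per site per unit branch length is 1 at stationarity.
    Transition probabilities are computed from a single symmetric
    eigendecomposition, which makes per-site scaled matrix exponentials
    cheap (one vector of eigenvalue exponentials per site).
    """

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray, name: str = "custom"):
        r = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if r.shape != (20, 20) or pi.shape != (20,):
            raise ValueError("need a 20x20 exchangeability matrix and 20 frequencies")
        if not np.allclose(r, r.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(pi <= 0):
            raise ValueError("frequencies must be positive")
        pi = pi / pi.sum()
        q = r * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.sum(pi * np.diag(q)))  # mean rate at stationarity
        q /= mu
        self.name = name
        self.frequencies = pi
        self.rate_matrix = q
        # symmetrize: B = D^{1/2} Q D^{-1/2} with D = diag(pi)
        s = np.sqrt(pi)
        b = (q * s[:, None]) / s[None, :]
        eigvals, u = np.linalg.eigh((b + b.T) / 2.0)
        self._eigvals = eigvals
        self._left = u / s[:, None]       # D^{-1/2} U
        self._right = u.T * s[None, :]    # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1."""
        if t < 0:
            raise ValueError("time must be >= 0")
        p = (self._left * np.exp(self._eigvals * t)[None, :]) @ self._right
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    def site_transition_rows(self, parent_states: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Per-site transition distributions: row ``i`` is P(times[i])[parent_states[i], :]."""
        ew = np.exp(np.outer(times, self._eigvals))           # (n_sites, 20)
        rows = (self._left[parent_states, :] * ew) @ self._right
        np.clip(rows, 0.0, None, out=rows)
        return rows / rows.sum(axis=1, keepdims=True)

    # -- presets -----------------------------------------------------------
    @classmethod
    def poisson(cls) -> "SubstitutionModel":
        r = np.ones((20, 20))
        np.fill_diagonal(r, 0.0)
        return cls(r, np.full(20, 1 / 20), name="poisson")

    @classmethod
    def blosum62(cls) -> "SubstitutionModel":
        blosum = substitution_matrices.load("BLOSUM62")
        idx = [blosum.alphabet.index(a) for a in AMINO_ACIDS]
        b = np.asarray(blosum)[np.ix_(idx, idx)]
        m = np.power(2.0, b / 2.0)  # implied odds ratios p_ij/(f_i f_j)
        # consistency: sum_j f_j m_ij = 1 recovers the background frequencies
        f = np.linalg.solve(m, np.ones(20))
        f = np.clip(f, 1e-6, None)
        f /= f.sum()
        r = m.copy()
        np.fill_diagonal(r, 0.0)
        return cls(r, f, name="blosum62")

    @classmethod
    def preset(cls, name: str) -> "SubstitutionModel":
        try:
            return {"poisson": cls.poisson, "blosum62": cls.blosum62}[name]()
        except KeyError:
            raise ValueError(f"unknown substitution preset: {name!r}") from None


@dataclass
class GeneFamilyAlignment:
    """Simulated sequences of one single-copy family, one per species.

    Sequences are aligned by construction (no indels) and stored as int8
    state arrays of identical length.
    """

    family_id: str
    sequences: dict[str, np.ndarray]
    site_rates: np.ndarray
    params: ReplicateParams

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        assert len(lengths) == 1, "family sequences must have identical length"

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> list[str]:
        return list(self.sequences)


def draw_site_rates(alpha: float, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. continuous gamma(shape=alpha, mean=1) site-rate draws."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return rng.gamma(shape=alpha, scale=1.0 / alpha, size=n_sites)


def evolve_branch(
    parent_seq: np.ndarray,
    branch_length: float,
    site_rates: np.ndarray,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve a sequence for ``branch_length`` expected substitutions per site.

    Site ``i`` evolves for time ``branch_length * site_rates[i]`` under the
    model; sites are independent given the rates.
    """
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    parent = np.asarray(parent_seq, dtype=np.intp)
    if len(site_rates) != len(parent):
        raise ValueError("need one site rate per site")
    if branch_length == 0:
        return parent.astype(np.int8)
    rows = model.site_transition_rows(parent, branch_length * np.asarray(site_rates))
    cum = np.cumsum(rows, axis=1)
    u = rng.random(len(parent)) * cum[:, -1]
    child = (cum < u[:, None]).sum(axis=1)
    return child.astype(np.int8)


def simulate_family(
    tree: PhyloTree,
    params: ReplicateParams,
    family_index: int,
    model: SubstitutionModel | None = None,
) -> GeneFamilyAlignment:
    """Simulate one family along ``tree`` scaled by the replicate's multiplier.

    The root sequence is drawn from the stationary frequencies; a single
    gamma rate vector is drawn per family. Deterministic given
    ``(params.rng_seed, family_index)`` (counter-based seeding), so families
    can be regenerated independently and in parallel.
    """
    if family_index >= params.n_genes:
        raise ValueError("family_index out of range for this replicate")
    model = model or SubstitutionModel.blosum62()
    rng = np.random.default_rng([params.rng_seed, family_index])
    scaled = scale_tree(tree, params.gene_rate_multiplier)
    length = params.sequence_lengths[family_index]
    rates = draw_site_rates(params.alpha, length, rng)
    root_seq = rng.choice(20, size=length, p=model.frequencies).astype(np.int8)

    sequences: dict[str, np.ndarray] = {}

    def recurse(node: Node, seq: np.ndarray) -> None:
        if node.is_leaf:
            sequences[node.name] = seq
            return
        for child in node.children:
            recurse(child, evolve_branch(seq, child.length, rates, model, rng))

    recurse(scaled.root, root_seq)
    return GeneFamilyAlignment(
        family_id=f"g{family_index}", sequences=sequences, site_rates=rates, params=params
    )


def simulate_replicate(
    tree: PhyloTree, params: ReplicateParams, model: SubstitutionModel | None = None
) -> list[GeneFamilyAlignment]:
    """All families of one replicate."""
    model = model or SubstitutionModel.blosum62()
    return [simulate_family(tree, params, i, model) for i in range(params.n_genes)]


# ---------------------------------------------------------------------------
# proteome I/O
# ---------------------------------------------------------------------------

def gene_id(species: str, family_id: str) -> str:
    return f"{species}|{family_id}"


def parse_gene_id(gid: str) -> tuple[str, str]:
    species, _, family = gid.partition("|")
    if not family:
        raise ValueError(f"gene id without family part: {gid!r}")
    return species, family


def write_proteomes(families: list[GeneFamilyAlignment], out_dir) -> list[Path]:
    """One FASTA per species; record ids ``<species>|g<family_index>``."""
    if not families:
        raise ValueError("no families to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species = families[0].species
    paths = []
    for sp in species:
        records = []
        seen = set()
        for fam in families:
            gid = gene_id(sp, fam.family_id)
            if gid in seen:
                raise ValueError(f"gene id collision: {gid}")
            seen.add(gid)
            records.append(SeqRecord(Seq(seq_to_str(fam.sequences[sp])), id=gid, description=""))
        path = out_dir / f"{sp}.fa"
        SeqIO.write(records, str(path), "fasta")
        paths.append(path)
    return paths


def read_proteomes(in_dir) -> dict[str, dict[str, np.ndarray]]:
    """Read per-species FASTAs back: {species: {gene_id: int8 sequence}}."""
    in_dir = Path(in_dir)
    out: dict[str, dict[str, np.ndarray]] = {}
    for path in sorted(in_dir.glob("*.fa")):
        species = path.stem
        out[species] = {
            rec.id: str_to_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        }
        if not out[species]:
            raise ValueError(f"empty proteome file: {path}")
    return out
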