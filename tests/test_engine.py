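"""Orthogroup inference engine: alignment scores, prefilter, graph, MCL."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orthosim.design import ReplicateParams
from orthosim.engine import (
    EngineConfig,
    Gene,
    SimilarityGraph,
    build_similarity_graph,
    filter_hits,
    genes_from_families,
    infer_orthogroups,
    kmer_prefilter,
    mcl_cluster,
    pair_score,
    self_score,
    score_matrix,
)
from orthosim.simulate import AMINO_ACIDS, SubstitutionModel, simulate_replicate
from orthosim.trees import generate_guide_tree

aa_text = st.text(alphabet=AMINO_ACIDS, min_size=10, max_size=60)


def random_seq(rng, n):
    return rng.integers(0, 20, n).astype(np.int8)


class TestPairScore:
    @given(aa_text)
    def test_self_alignment_is_diagonal_sum(self, s):
        # gap-free self alignment is optimal for a standard log-odds table
        sub = score_matrix()
        oracle = sum(int(sub[AMINO_ACIDS.index(c), AMINO_ACIDS.index(c)]) for c in s)
        assert pair_score(s, s) == oracle == self_score(s)

    @given(aa_text, aa_text)
    def test_symmetry(self, a, b):
        assert pair_score(a, b) == pair_score(b, a)

    def test_all_mismatch_floors_at_zero(self):
        # W/P scores -4 in BLOSUM62: the optimal local alignment is empty
        assert pair_score("WWWW", "PPPP") == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pair_score("", "ACD")

    def test_gap_beats_mismatch_when_cheaper(self):
        # alignment with one affine gap must outscore the no-gap alternative
        a, b = "AAAAWWWWAAAA", "AAAAAAAA"
        no_gap = pair_score(a[:4], b[:4])
        assert pair_score(a, b) > no_gap


class TestKmerPrefilter:
    def test_identical_sequences_pass(self):
        assert kmer_prefilter("ACDEFGHIK", "ACDEFGHIK", k=5, min_shared=3)

    def test_disjoint_alphabets_fail(self):
        assert not kmer_prefilter("AAAA", "CCCC", k=2, min_shared=1)

    @given(st.integers(0, 10**6))
    def test_matches_set_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACDE"), 30))
        b = "".join(rng.choice(list("ACDE"), 30))
        k, min_shared = 3, 2
        oracle = len(
            {a[i : i + k] for i in range(len(a) - k + 1)}
            & {b[i : i + k] for i in range(len(b) - k + 1)}
        )
        assert kmer_prefilter(a, b, k, min_shared) == (oracle >= min_shared)


def _identical_family_genes(n_species, n_fam, length, seed):
    """Families with identical sequences within each family, random across."""
    rng = np.random.default_rng(seed)
    genes = []
    for f in range(n_fam):
        seq = random_seq(rng, length)
        for s in range(n_species):
            genes.append(Gene(id=f"s{s}|g{f}", species=f"s{s}", family=f"g{f}", seq=seq))
    return genes


class TestSimilarityGraph:
    def test_identical_family_gives_complete_unit_clique(self):
        genes = _identical_family_genes(4, 1, 120, seed=0)
        g = build_similarity_graph(genes)
        assert g.n_edges == 6  # complete graph on 4 genes
        assert all(w == pytest.approx(1.0) for w in g.edges.values())

    @pytest.mark.parametrize("use_prefilter", [True, False])
    def test_unrelated_families_stay_disconnected(self, use_prefilter):
        genes = _identical_family_genes(4, 3, 150, seed=1)
        cfg = EngineConfig(use_prefilter=use_prefilter)
        g = build_similarity_graph(genes, cfg)
        for (a, b) in g.edges:
            assert a.split("|")[1] == b.split("|")[1]  # within-family only

    def test_no_self_edges(self):
        g = SimilarityGraph(nodes=["x"], species={"x": "s"})
        with pytest.raises(ValueError):
            g.add_edge("x", "x", 1.0)


class TestFilterHits:
    @pytest.fixture
    def toy(self):
        g = SimilarityGraph(
            nodes=["a|g0", "b|g0", "b|g1"],
            species={"a|g0": "a", "b|g0": "b", "b|g1": "b"},
        )
        g.add_edge("a|g0", "b|g0", 0.9)
        g.add_edge("a|g0", "b|g1", 0.5)
        return g

    def test_single_hit_always_retained(self):
        g = SimilarityGraph(nodes=["a|g0", "b|g0"], species={"a|g0": "a", "b|g0": "b"})
        g.add_edge("a|g0", "b|g0", 0.1)
        assert filter_hits(g, beta=1.0).n_edges == 1

    def test_beta_one_keeps_only_best_per_species(self, toy):
        kept = filter_hits(toy, beta=1.0)
        assert set(kept.edges) == {("a|g0", "b|g0")}

    def test_beta_zero_is_noop(self, toy):
        assert set(filter_hits(toy, beta=0.0).edges) == set(toy.edges)

    def test_relative_retention_window(self, toy):
        assert set(filter_hits(toy, beta=0.5).edges) == set(toy.edges)


def _graph_from_edges(nodes, edges):
    g = SimilarityGraph(nodes=list(nodes), species={n: n.split("|")[0] for n in nodes})
    for a, b, w in edges:
        g.add_edge(a, b, w)
    return g


def _mcl_dense_oracle(nodes, edges, inflation, iters=60):
    """Straight-line dense MCL (independent of the sparse implementation)."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.eye(n)
    for a, b, w in edges:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(iters):
        m = m @ m
        m = np.power(m, inflation)
        m /= m.sum(axis=0, keepdims=True)
    reach = (m + m.T) > 1e-9
    labels = -np.ones(n, dtype=int)
    for i in range(n):
        if labels[i] < 0:
            stack, labels[i] = [i], i
            while stack:
                j = stack.pop()
                for k in np.where(reach[j])[0]:
                    if labels[k] < 0:
                        labels[k] = i
                        stack.append(k)
    out = {}
    for node, lab in zip(nodes, labels):
        out.setdefault(lab, set()).add(node)
    return {frozenset(c) for c in out.values()}


class TestMCL:
    def test_disconnected_cliques_recovered_exactly(self):
        nodes, edges = [], []
        for block in range(2):
            members = [f"s{i}|g{block}" for i in range(5)]
            nodes.extend(members)
            edges.extend((a, b, 1.0) for a, b in itertools.combinations(members, 2))
        ogs = mcl_cluster(_graph_from_edges(nodes, edges), inflation=1.5)
        got = {frozenset(c) for c in ogs.clusters}
        assert got == {frozenset(f"s{i}|g{b}" for i in range(5)) for b in range(2)}

    def test_isolated_node_is_singleton(self):
        g = _graph_from_edges(["a|g0", "b|g0", "c|g1"], [("a|g0", "b|g0", 1.0)])
        ogs = mcl_cluster(g, inflation=2.0)
        assert [["c|g1"]] == [c for c in ogs.clusters if len(c) == 1]

    def test_path_graph_fixed_point_matches_dense_oracle(self):
        nodes = ["a|g0", "b|g0", "c|g0"]
        edges = [("a|g0", "b|g0", 1.0), ("b|g0", "c|g0", 1.0)]
        ogs = mcl_cluster(_graph_from_edges(nodes, edges), inflation=2.0)
        more = mcl_cluster(_graph_from_edges(nodes, edges), inflation=2.0, max_iter=110)
        assert ogs.converged and ogs.clusters == more.clusters
        assert {frozenset(c) for c in ogs.clusters} == _mcl_dense_oracle(nodes, edges, 2.0)

    def test_invalid_inflation(self):
        with pytest.raises(ValueError):
            mcl_cluster(_graph_from_edges(["a|g0", "b|g0"], []), inflation=1.0)

    def test_partition_property_on_random_graph(self):
        rng = np.random.default_rng(0)
        nodes = [f"s{i}|g{i}" for i in range(30)]
        edges = [
            (nodes[i], nodes[j], float(rng.random()))
            for i in range(30)
            for j in range(i + 1, 30)
            if rng.random() < 0.1
        ]
        ogs = mcl_cluster(_graph_from_edges(nodes, edges), inflation=1.5)
        assert sorted(g for c in ogs.clusters for g in c) == sorted(nodes)


@pytest.fixture(scope="module")
def slow_genes():
    tree = generate_guide_tree(8, seed=2)
    params = ReplicateParams(0, 0.2, 1.0, 6, (200,) * 6, 31)
    return genes_from_families(simulate_replicate(tree, params, SubstitutionModel.blosum62()))


class TestInferOrthogroups:
    def test_slow_regime_recovers_every_family(self, slow_genes):
        ogs, diag = infer_orthogroups(slow_genes)
        assert ogs.n_orthogroups == 6
        assert (ogs.sizes == 8).all()
        assert diag["purity"] == 1.0

    def test_fast_regime_fragments_but_never_merges(self):
        tree = generate_guide_tree(8, seed=2)
        params = ReplicateParams(0, 8.0, 1.0, 6, (200,) * 6, 31)
        genes = genes_from_families(
            simulate_replicate(tree, params, SubstitutionModel.blosum62())
        )
        ogs, diag = infer_orthogroups(genes)
        assert ogs.n_orthogroups > 6  # fragmentation = low recall
        assert diag["purity"] == 1.0  # precision stays ~1: no cross-family merges

    def test_component_oracle_with_thresholds_off(self):
        # families built from mutually penalized residues (W/P score < 0), so
        # the similarity graph is genuinely disconnected across families
        seqs = {"g0": "WGWWGWWGWW" * 12, "g1": "PKPPKPPKPP" * 12}
        genes = [
            Gene(id=f"s{i}|{f}", species=f"s{i}", family=f, seq=np.array(
                [AMINO_ACIDS.index(c) for c in seq], dtype=np.int8))
            for f, seq in seqs.items()
            for i in range(3)
        ]
        cfg = EngineConfig(use_prefilter=False, score_floor=0.0, beta=0.0)
        ogs, _ = infer_orthogroups(genes, cfg)
        # similarity graph is disconnected across families: clusters must
        # equal its connected components (the two families)
        assert {frozenset(c) for c in ogs.clusters} == {
            frozenset(f"s{i}|g{f}" for i in range(3)) for f in range(2)
        }

    def test_orthogroups_tsv_layout(self, slow_genes, tmp_path):
        ogs, _ = infer_orthogroups(slow_genes)
        path = tmp_path / "ogs.tsv"
        ogs.to_tsv(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + ogs.n_orthogroups
        assert lines[0].split("\t")[:2] == ["orthogroup", "size"]
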