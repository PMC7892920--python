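"""Sequence simulator: gamma rates, CTMC evolution, proteome I/O."""

import numpy as np
import pytest

from orthosim.design import ReplicateParams
from orthosim.simulate import (
    GeneFamilyAlignment,
    SubstitutionModel,
    draw_site_rates,
    evolve_branch,
    read_proteomes,
    seq_to_str,
    simulate_family,
    simulate_replicate,
    str_to_seq,
    write_proteomes,
)
from orthosim.trees import generate_guide_tree, parse_newick


@pytest.fixture(scope="module")
def poisson():
    return SubstitutionModel.poisson()


@pytest.fixture(scope="module")
def blosum():
    return SubstitutionModel.blosum62()


class TestSiteRates:
    def test_degenerate_gamma_limit(self):
        rates = draw_site_rates(1e6, 10_000, np.random.default_rng(0))
        assert np.abs(rates - 1).max() < 0.01

    def test_mean_one(self):
        rates = draw_site_rates(0.7, 100_000, np.random.default_rng(1))
        se = np.sqrt((1 / 0.7) / 100_000)
        assert abs(rates.mean() - 1.0) < 3 * se

    def test_variance_is_inverse_alpha(self):
        # gamma(shape a, mean 1): var = 1/a; var of the sample variance
        # ~ (mu4 - var^2)/n with mu4 = 3 a (a+2) theta^4
        a, n = 0.5, 100_000
        rates = draw_site_rates(a, n, np.random.default_rng(2))
        theta = 1 / a
        mu4 = 3 * a * (a + 2) * theta**4
        se = np.sqrt((mu4 - (1 / a) ** 2) / n)
        assert abs(rates.var(ddof=1) - 2.0) < 3 * se

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            draw_site_rates(0.0, 10, np.random.default_rng(0))


class TestModels:
    @pytest.mark.parametrize("preset", ["poisson", "blosum62"])
    def test_rate_matrix_is_proper_and_normalized(self, preset):
        m = SubstitutionModel.preset(preset)
        q, pi = m.rate_matrix, m.frequencies
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert -np.sum(pi * np.diag(q)) == pytest.approx(1.0)
        # detailed balance (time reversibility)
        flux = pi[:, None] * q
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)

    @pytest.mark.parametrize("preset", ["poisson", "blosum62"])
    def test_transition_matrix_reversible_and_stochastic(self, preset):
        m = SubstitutionModel.preset(preset)
        p = m.transition_matrix(0.73)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        flux = m.frequencies[:, None] * p
        np.testing.assert_allclose(flux, flux.T, atol=1e-10)

    def test_blosum_frequencies_plausible(self, blosum):
        # recovered background frequencies: positive, normalized, non-uniform
        f = blosum.frequencies
        assert f.sum() == pytest.approx(1.0)
        assert f.min() > 0.005 and f.max() < 0.15
        assert f.max() / f.min() > 2


class TestEvolveBranch:
    def test_zero_branch_is_identity(self, blosum):
        rng = np.random.default_rng(0)
        parent = rng.integers(0, 20, 300).astype(np.int8)
        child = evolve_branch(parent, 0.0, np.ones(300), blosum, rng)
        assert (child == parent).all()

    def test_poisson_closed_form_difference_fraction(self, poisson):
        # 20-state equal-rates model: P(differ) = (19/20)(1 - exp(-(20/19) t))
        t, n = 0.3, 100_000
        rng = np.random.default_rng(3)
        parent = rng.integers(0, 20, n).astype(np.int8)
        child = evolve_branch(parent, t, np.ones(n), poisson, rng)
        expected = (19 / 20) * (1 - np.exp(-(20 / 19) * t))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(np.mean(child != parent) - expected) < 3 * se

    def test_long_branch_reaches_stationarity(self, blosum):
        n = 100_000
        rng = np.random.default_rng(4)
        parent = np.zeros(n, dtype=np.int8)  # far from stationarity
        child = evolve_branch(parent, 50.0, np.ones(n), blosum, rng)
        freqs = np.bincount(child, minlength=20) / n
        se = np.sqrt(blosum.frequencies * (1 - blosum.frequencies) / n)
        assert (np.abs(freqs - blosum.frequencies) < 5 * se).all()

    def test_negative_branch_rejected(self, poisson):
        with pytest.raises(ValueError):
            evolve_branch(np.zeros(5, dtype=np.int8), -0.1, np.ones(5), poisson,
                          np.random.default_rng(0))


@pytest.fixture(scope="module")
def tree():
    return generate_guide_tree(8, seed=1)


class TestSimulateFamily:
    def test_vanishing_multiplier_freezes_sequences(self, tree, blosum):
        params = ReplicateParams(0, 1e-9, 1.0, 1, (150,), 7)
        fam = simulate_family(tree, params, 0, blosum)
        seqs = list(fam.sequences.values())
        assert all((s == seqs[0]).all() for s in seqs)

    def test_determinism(self, tree, blosum):
        params = ReplicateParams(0, 1.0, 0.5, 2, (120, 120), 99)
        a = simulate_family(tree, params, 1, blosum)
        b = simulate_family(tree, params, 1, blosum)
        assert all((a.sequences[sp] == b.sequences[sp]).all() for sp in a.sequences)

    def test_mean_identity_decreases_with_multiplier(self, tree, blosum):
        idents = []
        for mult in (0.2, 1.0, 5.0, 10.0):
            params = ReplicateParams(0, mult, 1.0, 30, (150,) * 30, 11)
            vals = []
            for i in range(30):
                fam = simulate_family(tree, params, i, blosum)
                seqs = list(fam.sequences.values())
                for a in range(len(seqs)):
                    for b in range(a + 1, len(seqs)):
                        vals.append(np.mean(seqs[a] == seqs[b]))
            idents.append(np.mean(vals))
        assert idents == sorted(idents, reverse=True)

    def test_divergence_increases_with_patristic_distance(self, blosum):
        from orthosim.pipeline import spearman_rho
        from orthosim.trees import patristic_matrix

        tree = generate_guide_tree(10, seed=6)
        params = ReplicateParams(0, 2.0, 1.0, 50, (120,) * 50, 13)
        labels, pmat = patristic_matrix(tree)
        div = np.zeros_like(pmat)
        for i in range(50):
            fam = simulate_family(tree, params, i, blosum)
            for a in range(len(labels)):
                for b in range(a + 1, len(labels)):
                    frac = np.mean(fam.sequences[labels[a]] != fam.sequences[labels[b]])
                    div[a, b] += frac
        iu = np.triu_indices(len(labels), k=1)
        assert spearman_rho(pmat[iu], div[iu]) > 0

    def test_equal_length_invariant_is_hard(self):
        params = ReplicateParams(0, 1.0, 1.0, 1, (10,), 0)
        with pytest.raises(AssertionError):
            GeneFamilyAlignment(
                family_id="g0",
                sequences={"a": np.zeros(10, dtype=np.int8), "b": np.zeros(9, dtype=np.int8)},
                site_rates=np.ones(10),
                params=params,
            )


class TestProteomeIO:
    def test_roundtrip_and_partition(self, tmp_path):
        tree = parse_newick("((A:0.1,B:0.1):0.1,C:0.1);")
        params = ReplicateParams(0, 1.0, 1.0, 4, (80,) * 4, 21)
        fams = simulate_replicate(tree, params, SubstitutionModel.poisson())
        paths = write_proteomes(fams, tmp_path)
        assert len(paths) == 3
        back = read_proteomes(tmp_path)
        assert set(back) == {"A", "B", "C"}
        for sp in back:
            assert len(back[sp]) == 4
            for fam in fams:
                gid = f"{sp}|{fam.family_id}"
                assert (back[sp][gid] == fam.sequences[sp]).all()
        # true-family labels partition genes into n_genes classes of size n_species
        families = {}
        for sp, records in back.items():
            for gid in records:
                families.setdefault(gid.split("|")[1], []).append(sp)
        assert len(families) == 4
        assert all(sorted(v) == ["A", "B", "C"] for v in families.values())

    def test_seq_string_roundtrip(self):
        seq = np.random.default_rng(0).integers(0, 20, 64).astype(np.int8)
        assert (str_to_seq(seq_to_str(seq)) == seq).all()
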