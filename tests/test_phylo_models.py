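import itertools

import numpy as np
import pytest

import _oracles
from conftest import random_gtr, random_tree_newick
from crstool.phylo_models import (
    CANONICAL_PAIRS,
    PAIR16_INDEX,
    PhyloTree,
    build_gtr,
    build_pair_model,
    column_likelihood,
    column_likelihoods,
    default_pair_model,
    encode_observations,
    estimate_gtr,
    evolve_states,
    gtr_distance,
    jukes_cantor,
    transition_matrix,
)


class TestBuildGtr:
    def test_jukes_cantor_off_diagonals(self, jc):
        off = jc.Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1 / 3)

    def test_detailed_balance_random(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = random_gtr(rng)
            flux = m.pi[:, None] * m.Q
            assert np.allclose(flux, flux.T, atol=1e-12)

    def test_normalization_exact(self):
        m = build_gtr([0.7, 0.1, 0.1, 0.1], np.ones(6))
        # direct arithmetic: expected rate -sum_i pi_i Q_ii must be 1
        assert -np.sum(m.pi * np.diag(m.Q)) == pytest.approx(1.0, abs=1e-12)

    def test_rejects_bad_pi(self):
        with pytest.raises(ValueError):
            build_gtr([0.5, 0.5, 0.1, 0.1], np.ones(6))
        with pytest.raises(ValueError):
            build_gtr([0.25, 0.25, 0.25, 0.25], [1, 1, 1, 1, 1, -1])


class TestPairModel:
    def test_independence_from_jc_uniform(self, jc):
        m = build_pair_model(from_single=jc)
        assert np.allclose(m.pi, 1 / 16)
        assert m.independent

    def test_default_bias_canonical_mass(self):
        m = default_pair_model()
        mass = sum(m.pi[PAIR16_INDEX[p]] for p in CANONICAL_PAIRS)
        assert mass > 0.5

    def test_detailed_balance_16(self):
        rng = np.random.default_rng(7)
        single = random_gtr(rng)
        m = build_pair_model(from_single=single, stacking_bias={"GC": 5.0, "CG": 5.0})
        flux = m.pi[:, None] * m.Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_bad_bias_rejected(self, jc):
        with pytest.raises(ValueError):
            build_pair_model(from_single=jc, stacking_bias={"GC": 0.0})


class TestTransitionMatrix:
    def test_identity_at_zero(self, jc):
        assert np.allclose(transition_matrix(jc, 0.0), np.eye(4), atol=1e-12)

    def test_rows_stochastic(self, jc):
        P = transition_matrix(jc, 0.37)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= 0)

    def test_semigroup(self, jc):
        P = transition_matrix(jc, 0.2) @ transition_matrix(jc, 0.3)
        assert np.allclose(P, transition_matrix(jc, 0.5), atol=1e-8)

    def test_negative_t_rejected(self, jc):
        with pytest.raises(ValueError):
            transition_matrix(jc, -0.1)


class TestColumnLikelihood:
    def test_zero_branch_lengths(self, jc):
        t = PhyloTree.from_newick("(A:0.0,B:0.0);")
        lik = column_likelihood(t, {"A": "A", "B": "A"}, jc)
        assert lik == pytest.approx(0.25, abs=1e-12)

    def test_stationarity_limit(self, jc):
        t = PhyloTree.from_newick("(A:50.0,B:50.0);")
        lik = column_likelihood(t, {"A": "A", "B": "A"}, jc)
        assert lik == pytest.approx(0.25**2, abs=1e-6)

    def test_brute_force_3_leaves(self, jc):
        rng = np.random.default_rng(11)
        for _ in range(20):
            nwk = random_tree_newick(rng, 3)
            t = PhyloTree.from_newick(nwk)
            obs = {name: "ACGU"[rng.integers(4)] for name in t.leaves}
            got = column_likelihood(t, obs, jc)
            exp = _oracles.brute_force_column_likelihood(t, obs, jc)
            assert got == pytest.approx(exp, abs=1e-10)

    def test_missing_leaf_marginalized(self, tree3, jc):
        partial = column_likelihood(tree3, {"A": "A"}, jc)
        full = sum(
            column_likelihood(tree3, {"A": "A", "B": b, "C": c}, jc)
            for b in "ACGU"
            for c in "ACGU"
        )
        assert partial == pytest.approx(full, abs=1e-12)

    def test_unknown_leaf_error(self, tree3, jc):
        with pytest.raises(KeyError):
            column_likelihood(tree3, {"Z": "A"}, jc)

    def test_total_probability_small_trees(self, jc):
        t = PhyloTree.from_newick("((A:0.3,B:0.7):0.2,C:0.4);")
        total = sum(
            column_likelihood(t, dict(zip("ABC", s)), jc)
            for s in itertools.product("ACGU", repeat=3)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_total_probability_pair_model(self):
        m = default_pair_model()
        t = PhyloTree.from_newick("(A:0.3,B:0.6);")
        total = sum(
            column_likelihood(t, {"A": a, "B": b}, m)
            for a in m.alphabet
            for b in m.alphabet
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_leaf_order_invariance(self, tree3, jc):
        obs = {"A": "G", "B": "C", "C": "U"}
        l1 = column_likelihood(tree3, obs, jc)
        l2 = column_likelihood(tree3, dict(reversed(list(obs.items()))), jc)
        assert l1 == l2


class TestFactorization:
    def test_independence_model_factorizes(self, jc):
        rng = np.random.default_rng(3)
        pair = build_pair_model(from_single=jc)
        for _ in range(25):
            t = PhyloTree.from_newick(random_tree_newick(rng, int(rng.integers(2, 5))))
            singles = {name: ("ACGU"[rng.integers(4)], "ACGU"[rng.integers(4)]) for name in t.leaves}
            lp = column_likelihood(t, {k: a + b for k, (a, b) in singles.items()}, pair)
            l1 = column_likelihood(t, {k: a for k, (a, b) in singles.items()}, jc)
            l2 = column_likelihood(t, {k: b for k, (a, b) in singles.items()}, jc)
            assert lp == pytest.approx(l1 * l2, abs=1e-10)


class TestGtrDistance:
    def test_identical(self, jc):
        assert gtr_distance("ACGUACGU", "ACGUACGU", jc) == 0.0

    def test_jc_closed_form(self, jc):
        seq1 = "A" * 100
        seq2 = "C" * 10 + "A" * 90
        d = gtr_distance(seq1, seq2, jc)
        assert d == pytest.approx(_oracles.jc_distance(0.1), abs=1e-4)

    def test_gaps_dropped(self, jc):
        d = gtr_distance("AC-GU", "ACAGU", jc)
        assert d == 0.0

    def test_saturation_warns(self, jc):
        with pytest.warns(UserWarning, match="saturated"):
            d = gtr_distance("ACGU" * 10, "CAUG" * 10, jc)
        assert d == float("inf")

    def test_recovery_simulation(self):
        rng = np.random.default_rng(123)
        model = build_gtr([0.3, 0.2, 0.3, 0.2], [1.0, 2.0, 1.0, 1.0, 2.0, 1.0])
        t_true = 0.2
        n = 10_000
        x = rng.choice(4, size=n, p=model.pi)
        P = model.transition_matrix(t_true)
        y = np.array([rng.choice(4, p=P[xi]) for xi in x])
        s1 = "".join("ACGU"[i] for i in x)
        s2 = "".join("ACGU"[i] for i in y)
        assert gtr_distance(s1, s2, model) == pytest.approx(t_true, abs=0.02)

    def test_no_comparable_columns(self, jc):
        with pytest.raises(ValueError):
            gtr_distance("--", "AC", jc)


class TestEstimateGtr:
    def test_parameter_recovery(self, tree8):
        rng = np.random.default_rng(2024)
        true = build_gtr([0.4, 0.15, 0.25, 0.2], [1, 3, 1, 1, 3, 1])
        obs = evolve_states(tree8, true, 3000, rng)
        fitted = estimate_gtr(obs, tree8)
        assert np.allclose(fitted.pi, true.pi, atol=0.03)

    def test_monomorphic_error(self, tree8):
        obs = np.zeros((8, 50), dtype=np.int64)
        with pytest.raises(ValueError, match="monomorphic"):
            estimate_gtr(obs, tree8)

    def test_beats_jc_start(self, tree8, jc):
        rng = np.random.default_rng(5)
        true = build_gtr([0.5, 0.1, 0.3, 0.1], np.ones(6))
        obs = evolve_states(tree8, true, 500, rng)
        fitted = estimate_gtr(obs, tree8)
        ll_fit = np.log(column_likelihoods(tree8, obs, fitted)).sum()
        ll_jc = np.log(column_likelihoods(tree8, obs, jc)).sum()
        assert ll_fit >= ll_jc - 1e-9


class TestTree:
    def test_duplicate_leaf_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PhyloTree.from_newick("(A:0.1,A:0.2);")

    def test_encode_observations_shape(self, tree3, jc):
        obs = encode_observations(tree3, [{"A": "A", "B": "-", "C": "G"}], jc)
        assert obs.shape == (3, 1)
        assert obs[tree3.leaves.index("B"), 0] == -1
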