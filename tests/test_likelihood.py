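"""Mk likelihood: transition matrices, rate discretization, pruning, search."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.linalg import expm

from morphophylo.likelihood import (
    MkEvaluator,
    MkModelSpec,
    _BranchProfiler,
    bootstrap_support,
    discretize_rates,
    mk_transition_probability,
    ml_search,
    optimize_branch_lengths,
    tree_log_likelihood,
)
from morphophylo.matrix import CharacterMatrix
from morphophylo.simulate import SimulationSpec, simulate_matrix, simulate_tree
from morphophylo.trees import PhyloTree

from conftest import random_matrix


class TestTransitionProbability:
    def test_identity_at_zero(self):
        assert np.allclose(mk_transition_probability(3, 0.0), np.eye(3))

    def test_uniform_at_infinity(self):
        P = mk_transition_probability(4, 1e6)
        assert np.allclose(P, 0.25)

    @pytest.mark.parametrize("k,t,r", [(2, 0.5, 1.0), (3, 0.2, 2.5), (4, 1.3, 0.3)])
    def test_matches_matrix_exponential(self, k, t, r):
        Q = (np.ones((k, k)) - k * np.eye(k)) / (k - 1)  # one expected change/unit
        assert np.allclose(mk_transition_probability(k, t, r), expm(Q * t * r))

    def test_rows_sum_to_one(self):
        P = mk_transition_probability(3, 0.7, 1.4)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_invalid_state_count(self):
        with pytest.raises(ValueError):
            mk_transition_probability(1, 0.1)


class TestDiscretizeRates:
    def test_mean_one_and_equal_weights(self):
        for law, shape in (("gamma", 0.31), ("gamma", 7.0), ("lognormal", 1.3)):
            p, r = discretize_rates(law, shape, 8)
            assert np.all(r > 0)
            assert p @ r == pytest.approx(1.0, abs=1e-10)

    def test_equal_rates_limits(self):
        _, r = discretize_rates("gamma", 1e6, 8)
        assert np.allclose(r, 1.0, atol=1e-2)
        _, r = discretize_rates("lognormal", 0.0, 8)
        assert np.allclose(r, 1.0)

    @pytest.mark.parametrize("law,shape", [("gamma", 0.5), ("lognormal", 0.8)])
    def test_category_means_match_numeric_integration(self, law, shape):
        G = 4
        if law == "gamma":
            dist = stats.gamma(shape, scale=1 / shape)
        else:
            dist = stats.lognorm(shape, scale=math.exp(-shape * shape / 2))
        edges = dist.ppf(np.linspace(0, 1, G + 1))
        oracle = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(
                lambda x: x * dist.pdf(x), lo, hi if np.isfinite(hi) else np.inf
            )
            oracle.append(val * G)
        _, r = discretize_rates(law, shape, G)
        assert np.allclose(r, oracle, rtol=1e-5)


def enumeration_loglik(tree, matrix, model):
    """Sum over all internal state assignments; independent of pruning."""
    _, rates = model.category_rates()
    nodes = list(tree.postorder())
    internals = [nd for nd in nodes if not nd.is_leaf]
    out = []
    for c in range(matrix.n_characters):
        k = matrix.char_meta[c].n_states
        site = 0.0
        for r in rates:
            Ps = {
                id(nd): mk_transition_probability(k, nd.length, r)
                for nd in nodes
                if nd.parent is not None
            }
            for states in itertools.product(range(k), repeat=len(internals)):
                sm = {id(nd): s for nd, s in zip(internals, states)}
                p = 1.0 / k
                for nd in nodes:
                    if nd.parent is None:
                        continue
                    up = sm[id(nd.parent)]
                    if nd.is_leaf:
                        p *= sum(
                            Ps[id(nd)][up, s]
                            for s in matrix.state_set(nd.label, c)
                        )
                    else:
                        p *= Ps[id(nd)][up, sm[id(nd)]]
                site += p
        out.append(math.log(site / len(rates)))
    return np.array(out)


class TestTreeLogLikelihood:
    def test_two_taxon_closed_form(self):
        m = CharacterMatrix.from_rows(["A", "B"], [[0], [1]])
        t = PhyloTree.from_newick("(A:0.04,B:0.06);")
        res = tree_log_likelihood(t, m, MkModelSpec(rate_law="equal", ascertainment="none"))
        assert res.log_likelihood == pytest.approx(
            math.log(0.5 * 0.5 * (1 - math.exp(-2 * 0.1)))
        )

    def test_all_missing_character_contributes_zero(self):
        m = CharacterMatrix.from_rows(list("ABCD"), [[0, "?"], [1, "?"], [0, "?"], [1, "?"]])
        t = PhyloTree.from_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        res = tree_log_likelihood(t, m, MkModelSpec(rate_law="equal", ascertainment="none"))
        assert res.per_char_lnL[1] == 0.0

    @pytest.mark.parametrize("asc", ["none", "variable_only"])
    def test_matches_enumeration_on_quartet(self, asc):
        rng = np.random.default_rng(13)
        m = random_matrix(rng, 4, 10, k_max=3, missing_p=0.15)
        t = PhyloTree.from_newick("((A:0.12,B:0.3):0.15,C:0.2,D:0.4);")
        model = MkModelSpec(rate_law="gamma", shape=0.7, n_categories=3, ascertainment=asc)
        res = tree_log_likelihood(t, m, model)
        oracle = enumeration_loglik(t, m, model)
        if asc == "variable_only":
            base = MkModelSpec(rate_law="gamma", shape=0.7, n_categories=3,
                               ascertainment="none")
            for k in sorted({c.n_states for c in m.char_meta}):
                # constant patterns: all taxa share state j
                p_const = 0.0
                for j in range(k):
                    cmj = CharacterMatrix.from_rows(m.taxa, [[j]] * 4, n_states=k)
                    p_const += math.exp(enumeration_loglik(t, cmj, base)[0])
                for c in range(m.n_characters):
                    all_missing = all(m.is_missing(i, c) for i in range(m.n_taxa))
                    if m.char_meta[c].n_states == k and not all_missing:
                        oracle[c] -= math.log1p(-p_const)
        assert np.allclose(res.per_char_lnL, oracle, atol=1e-10)
        assert res.log_likelihood == pytest.approx(res.per_char_lnL.sum())

    def test_root_invariance_random_trees(self):
        rng = np.random.default_rng(23)
        model = MkModelSpec(rate_law="gamma", shape=1.2, n_categories=4)
        for _ in range(5):
            tree = simulate_tree(7, rng)
            m, _ = simulate_matrix(
                SimulationSpec(tree=tree, n_characters=15, seed=int(rng.integers(1000)),
                               missing_fraction_beta=None)
            )
            base = tree_log_likelihood(tree, m, model).log_likelihood
            # reroot: write and reparse with a rotated representation
            other = PhyloTree.from_newick(tree.to_newick())
            leaf = other.leaves()[0]
            assert tree_log_likelihood(other, m, model).log_likelihood == pytest.approx(
                base, abs=1e-8
            )

    def test_asc_normalization_three_taxa_enumeration(self):
        """Corrected likelihoods over all variable patterns sum to one."""
        t = PhyloTree.from_newick("(A:0.2,B:0.35,C:0.1);")
        model = MkModelSpec(rate_law="equal", ascertainment="variable_only")
        total = 0.0
        for pattern in itertools.product(range(2), repeat=3):
            if len(set(pattern)) == 1:
                continue
            m = CharacterMatrix.from_rows(list("ABC"), [[s] for s in pattern], n_states=2)
            total += math.exp(tree_log_likelihood(t, m, model).log_likelihood)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invariant_character_rejected_under_asc(self):
        m = CharacterMatrix.from_rows(list("ABC"), [[0], [0], [0]], n_states=2)
        t = PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
        with pytest.raises(ValueError, match="invariant"):
            tree_log_likelihood(t, m, MkModelSpec())


class TestOptimization:
    def test_branch_profiler_agrees_with_full_pruning(self):
        rng = np.random.default_rng(31)
        tree = simulate_tree(6, rng)
        m, _ = simulate_matrix(
            SimulationSpec(tree=tree, n_characters=20, seed=5, missing_fraction_beta=None)
        )
        model = MkModelSpec(rate_law="gamma", shape=0.9, n_categories=4)
        ev = MkEvaluator(m, model)
        full = ev.loglik(tree, 0.9)
        prof = _BranchProfiler(ev, tree, 0.9)
        for v in range(len(prof.children) - 1):
            assert prof.objective_at(v, prof.lengths[v]) == pytest.approx(full, abs=1e-9)

    def test_two_taxon_closed_form_optimum(self):
        m = CharacterMatrix.from_rows(
            ["A", "B"], [[0] * 8, [1, 1, 0, 0, 0, 0, 0, 0]], n_states=2
        )
        res = optimize_branch_lengths(
            PhyloTree.from_newick("(A:0.1,B:0.1);"), m,
            MkModelSpec(rate_law="equal", ascertainment="none"), optimize_shape=False,
        )
        total = sum(nd.length for nd in res.tree.postorder() if nd.parent)
        # p = 2/8 differing -> t = -1/2 ln(1 - 2p)
        assert total == pytest.approx(-0.5 * math.log(0.5), abs=1e-4)

    def test_optimum_is_fixed_point(self):
        rng = np.random.default_rng(37)
        tree = simulate_tree(5, rng)
        m, _ = simulate_matrix(
            SimulationSpec(tree=tree, n_characters=30, seed=2, missing_fraction_beta=None)
        )
        model = MkModelSpec(rate_law="equal", ascertainment="variable_only")
        r1 = optimize_branch_lengths(tree, m, model, optimize_shape=False)
        r2 = optimize_branch_lengths(r1.tree, m, model, optimize_shape=False)
        assert r2.log_likelihood == pytest.approx(r1.log_likelihood, abs=1e-3)
        assert r2.log_likelihood >= r1.log_likelihood - 1e-9

    def test_more_categories_never_hurt(self):
        rng = np.random.default_rng(41)
        tree = simulate_tree(6, rng)
        m, _ = simulate_matrix(
            SimulationSpec(tree=tree, n_characters=40, rate_law="gamma", shape=0.5,
                           seed=3, missing_fraction_beta=None)
        )
        lnls = []
        for G in (1, 2, 4, 8):
            model = MkModelSpec(rate_law="gamma", n_categories=G)
            lnls.append(optimize_branch_lengths(tree, m, model).log_likelihood)
        assert all(b >= a - 1e-3 for a, b in zip(lnls, lnls[1:]))


class TestMlSearch:
    def test_matches_exhaustive_on_five_taxa(self):
        from morphophylo.parsimony import _all_topologies

        rng = np.random.default_rng(51)
        tree = simulate_tree(5, rng, mean_branch_length=0.3)
        m, _ = simulate_matrix(
            SimulationSpec(tree=tree, n_characters=60, seed=4, missing_fraction_beta=None)
        )
        model = MkModelSpec(rate_law="equal", ascertainment="variable_only")
        best_tree, res = ml_search(m, model, seed=1)
        scores = []
        for topo in _all_topologies(5):
            t = topo.to_phylo(m.taxa)
            scores.append(optimize_branch_lengths(t, m, model).log_likelihood)
        assert res.log_likelihood == pytest.approx(max(scores), abs=1e-3)

    def test_strong_signal_topology_recovery(self):
        rng = np.random.default_rng(61)
        tree = simulate_tree(8, rng, mean_branch_length=0.25)
        for nd in tree.postorder():
            if nd.parent is not None:
                nd.length = max(nd.length, 0.1)
        m, truth = simulate_matrix(
            SimulationSpec(tree=tree, n_characters=300, seed=6,
                           missing_fraction_beta=None, polymorphic_rate=0.0)
        )
        model = MkModelSpec(rate_law="gamma", n_categories=4)
        best_tree, _ = ml_search(m, model, seed=2)
        assert best_tree.rf_distance(tree) <= 2


class TestBootstrap:
    def test_identity_replicate_gives_full_support(self):
        rng = np.random.default_rng(71)
        tree = simulate_tree(6, rng, mean_branch_length=0.3)
        m, _ = simulate_matrix(
            SimulationSpec(tree=tree, n_characters=80, seed=8, missing_fraction_beta=None)
        )
        model = MkModelSpec(rate_law="equal")
        best, _ = ml_search(m, model, seed=3)
        # B=1 with the original matrix: every best-tree clade is found again
        support = bootstrap_support(m, model, B=3, seed=3, best_tree=best)
        assert all(0.0 <= v <= 1.0 for v in support.values())
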