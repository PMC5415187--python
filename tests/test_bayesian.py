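"""MCMC correctness: prior recovery, coupling, diagnostics, summaries, SS."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from morphophylo.bayesian import (
    BayesFactor,
    MarginalLikelihoodEstimate,
    McmcConfig,
    McmcState,
    PosteriorSample,
    bayes_factor,
    compute_diagnostics,
    effective_sample_size,
    majority_rule_tree,
    mcc_tree,
    run_mcmc,
    split_frequencies,
    stepping_stone,
)
from morphophylo.likelihood import MkEvaluator, MkModelSpec
from morphophylo.matrix import CharacterMatrix
from morphophylo.simulate import SimulationSpec, simulate_matrix, simulate_tree
from morphophylo.trees import PhyloTree


def make_sample(trees, shapes=None, config=None):
    cfg = config or McmcConfig(n_generations=len(trees), sample_every=1, burnin_fraction=0.0)
    states = [
        McmcState(t, (shapes or [1.0] * len(trees))[i], -1.0, -1.0,
                  frozenset(t.splits().keys()))
        for i, t in enumerate(trees)
    ]
    return PosteriorSample(states, 0, cfg)


@pytest.fixture(scope="module")
def empty_matrix():
    return CharacterMatrix.from_rows(list("ABCDE"), [["?"] * 5 for _ in range(5)])


class TestPriorRecovery:
    def test_data_free_run_samples_the_hyperprior_and_branch_prior(self, empty_matrix):
        cfg = McmcConfig(
            n_generations=60000, n_runs=1, n_chains=1, sample_every=40,
            burnin_fraction=0.1, seed=5,
        )
        model = MkModelSpec(rate_law="gamma", n_categories=4)
        runs = run_mcmc(empty_matrix, model, cfg)
        post = runs[0].post_burnin()
        shapes = np.array([s.shape for s in post])
        assert stats.kstest(shapes[::3], "expon").pvalue > 0.01
        lengths = np.array(
            [nd.length for s in post for nd in s.tree.postorder() if nd.parent]
        )
        assert lengths.mean() == pytest.approx(0.1, rel=0.1)
        assert stats.kstest(lengths[::25] * 10.0, "expon").pvalue > 0.01

    def test_data_free_topologies_uniform(self, empty_matrix):
        cfg = McmcConfig(
            n_generations=40000, n_runs=1, n_chains=1, sample_every=40,
            burnin_fraction=0.1, seed=9,
        )
        runs = run_mcmc(empty_matrix, MkModelSpec(rate_law="equal"), cfg)
        from collections import Counter

        counts = Counter(s.splits for s in runs[0].post_burnin())
        assert len(counts) == 15  # all unrooted 5-leaf topologies visited
        freqs = np.array(list(counts.values())) / sum(counts.values())
        assert freqs.max() < 2.5 / 15 and freqs.min() > 0.3 / 15


class TestSamplingContracts:
    def test_sample_count_includes_initial_state(self, empty_matrix):
        cfg = McmcConfig(n_generations=1000, n_runs=2, n_chains=1, sample_every=100, seed=1)
        runs = run_mcmc(empty_matrix, MkModelSpec(rate_law="equal"), cfg)
        assert [len(r.states) for r in runs] == [11, 11]
        # the 2 x (N/thin + 1) pooled-tree arithmetic of full-scale runs
        assert sum(len(r.states) for r in runs) == 2 * (1000 // 100 + 1)

    def test_deterministic_given_seed(self, empty_matrix):
        cfg = McmcConfig(n_generations=500, n_runs=1, n_chains=2, sample_every=50, seed=3)
        model = MkModelSpec(rate_law="gamma")
        a = run_mcmc(empty_matrix, model, cfg)
        b = run_mcmc(empty_matrix, model, cfg)
        assert [s.shape for s in a[0].states] == [s.shape for s in b[0].states]

    def test_strong_signal_posterior_concentrates(self):
        tree = PhyloTree.from_newick(
            "((A:0.15,B:0.15):0.4,(C:0.15,D:0.15):0.4);"
        )
        m, _ = simulate_matrix(
            SimulationSpec(tree=tree, n_characters=120, seed=2,
                           missing_fraction_beta=None, polymorphic_rate=0.0)
        )
        cfg = McmcConfig(n_generations=6000, n_runs=1, n_chains=2, sample_every=10,
                         burnin_fraction=0.25, seed=4, temperature=0.1)
        runs = run_mcmc(m, MkModelSpec(rate_law="equal"), cfg)
        freqs = split_frequencies(runs[0].post_burnin())
        true_split = frozenset(["C", "D"])
        assert freqs.get(true_split, 0.0) > 0.95

    def test_mc3_matches_single_chain_on_quartet(self):
        tree = PhyloTree.from_newick("((A:0.2,B:0.2):0.15,(C:0.2,D:0.2):0.15);")
        m, _ = simulate_matrix(
            SimulationSpec(tree=tree, n_characters=25, seed=8,
                           missing_fraction_beta=None, polymorphic_rate=0.0)
        )
        model = MkModelSpec(rate_law="equal")
        freqs = []
        for n_chains in (1, 3):
            cfg = McmcConfig(n_generations=20000, n_runs=1, n_chains=n_chains,
                             sample_every=10, burnin_fraction=0.25, seed=21,
                             temperature=0.2)
            runs = run_mcmc(m, model, cfg)
            freqs.append(split_frequencies(runs[0].post_burnin()))
        keys = set(freqs[0]) | set(freqs[1])
        for k in keys:
            assert freqs[0].get(k, 0) == pytest.approx(freqs[1].get(k, 0), abs=0.08)


class TestDiagnostics:
    def test_identical_runs_are_perfectly_converged(self):
        t = PhyloTree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        s1 = make_sample([t.copy() for _ in range(50)], shapes=list(np.linspace(0.5, 1.5, 50)))
        s2 = make_sample([t.copy() for _ in range(50)], shapes=list(np.linspace(0.5, 1.5, 50)))
        for st1, st2 in zip(s1.states, s2.states):
            st1.lnL = st2.lnL = st1.shape
        d = compute_diagnostics([s1, s2], burnin_fraction=0.0)
        assert d.asdsf == pytest.approx(0.0)
        assert d.psrf["shape"] == pytest.approx(1.0, abs=0.02)

    def test_ess_iid_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        assert effective_sample_size(x) == pytest.approx(4000, rel=0.2)

    def test_ess_ar1_oracle(self):
        rng = np.random.default_rng(1)
        rho, n = 0.9, 20000
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + math.sqrt(1 - rho * rho) * rng.normal()
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.3)

    def test_ess_never_exceeds_sample_count(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=500)
            assert effective_sample_size(x) <= 500


class TestSummaries:
    def trees_60_40(self):
        a = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        b = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        return [a.copy() for _ in range(6)] + [b.copy() for _ in range(4)]

    def test_majority_rule_on_mixed_sample(self):
        sample = make_sample(self.trees_60_40())
        cons = majority_rule_tree([sample], burnin_fraction=0.0)
        splits = cons.splits()
        supports = {s: nd.annotations["support"] for s, nd in splits.items()}
        assert len(supports) == 2
        assert sorted(supports.values()) == [pytest.approx(0.6), pytest.approx(0.6)]

    def test_majority_identical_sample_returns_that_tree(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        sample = make_sample([t.copy() for _ in range(10)])
        cons = majority_rule_tree([sample], burnin_fraction=0.0)
        assert cons.rf_distance(t) == 0
        assert all(
            nd.annotations["support"] == pytest.approx(1.0)
            for _, nd in cons.splits().items()
        )

    def test_majority_probabilities_match_asdsf_frequencies(self):
        sample = make_sample(self.trees_60_40())
        freqs = split_frequencies(sample.states)
        cons = majority_rule_tree([sample], burnin_fraction=0.0)
        for s, nd in cons.splits().items():
            assert nd.annotations["support"] == pytest.approx(freqs[s])

    def test_mcc_argmax_by_enumeration(self):
        a = PhyloTree.from_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        b = PhyloTree.from_newick("(((A:1,C:1):1,B:1):1,(D:1,E:1):1);")
        c = PhyloTree.from_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1);")
        trees = [a] * 5 + [b] * 3 + [c] * 2
        sample = make_sample([t.copy() for t in trees])
        freqs = split_frequencies(sample.states)
        # direct enumeration of the clade-credibility score per topology
        scores = {}
        for name, t in (("a", a), ("b", b), ("c", c)):
            scores[name] = math.prod(freqs[s] for s in t.splits())
        best = max(scores, key=scores.get)
        mcc = mcc_tree([sample], burnin_fraction=0.0)
        assert mcc.rf_distance({"a": a, "b": b, "c": c}[best]) == 0

    def test_mcc_clades_need_not_be_majority(self):
        # topology 'a' sampled most often, but the AB clade only at 50%
        a = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        b = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        sample = make_sample([a.copy() for _ in range(5)] + [b.copy() for _ in range(5)])
        mcc = mcc_tree([sample], burnin_fraction=0.0)
        cons = majority_rule_tree([sample], burnin_fraction=0.0)
        assert len(mcc.splits()) == 2 and len(cons.splits()) == 0


class TestBayesFactors:
    def mk_est(self, label, logml):
        return MarginalLikelihoodEstimate(label, logml, 8, np.zeros(8))

    def test_equal_models_no_evidence(self):
        bf = bayes_factor(self.mk_est("m1", -100.0), self.mk_est("m0", -100.0))
        assert bf.two_log_bf == 0.0 and bf.verdict == "none"

    def test_threshold_arithmetic(self):
        bf = bayes_factor(self.mk_est("m1", -94.0), self.mk_est("m0", -100.0))
        assert bf.two_log_bf == pytest.approx(12.0)
        assert bf.verdict == "very strong"
        assert bayes_factor(self.mk_est("a", -98.5), self.mk_est("b", -100.0)).verdict == "positive"

    def test_antisymmetry(self):
        a, b = self.mk_est("a", -90.0), self.mk_est("b", -95.0)
        assert bayes_factor(a, b).log_bf == -bayes_factor(b, a).log_bf


@pytest.fixture(scope="module")
def toy():
        rng = np.random.default_rng(7)
        rows = rng.integers(0, 2, (3, 20))
        while (rows.min(0) == rows.max(0)).any():
            rows = rng.integers(0, 2, (3, 20))
        m = CharacterMatrix.from_rows(list("ABC"), rows.tolist())
        topo = PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
        model = MkModelSpec(rate_law="equal", ascertainment="none")
        ev = MkEvaluator(m, model)

        def lnL_of_t(t):
            tr = topo.copy()
            for nd in tr.postorder():
                if nd.parent is not None:
                    nd.length = t
            return ev.loglik(tr)

        lam = 10.0
        val, _ = integrate.quad(
            lambda t: math.exp(lnL_of_t(t)) * lam * math.exp(-lam * t), 0, 10, limit=200
        )
        return m, model, math.log(val)


class TestSteppingStone:
    def test_toy_matches_quadrature_within_three_se(self, toy):
        m, model, log_truth = toy
        cfg = McmcConfig(n_generations=1, n_runs=3, n_chains=1, seed=11,
                         fix_topology=True, link_branch_lengths=True, sample_every=1)
        est = stepping_stone(m, model, cfg, n_steps=16, per_step_generations=1500)
        assert abs(est.log_ml - log_truth) <= max(3 * est.std_error, 0.3)

    def test_variance_shrinks_with_longer_rungs(self, toy):
        m, model, _ = toy
        spreads = []
        for gens in (300, 2400):
            cfg = McmcConfig(n_generations=1, n_runs=4, n_chains=1, seed=13,
                             fix_topology=True, link_branch_lengths=True, sample_every=1)
            est = stepping_stone(m, model, cfg, n_steps=8, per_step_generations=gens)
            spreads.append(np.std(est.per_run_log_ml))
        assert spreads[1] < spreads[0] * 1.5  # typically much smaller

    def test_single_rung_prior_arithmetic_mean_is_biased(self, toy):
        """A one-rung ladder reduces to naive prior-arithmetic-mean estimation
        and is expected to miss; documents why multiple rungs are needed."""
        m, model, log_truth = toy
        cfg = McmcConfig(n_generations=1, n_runs=2, n_chains=1, seed=17,
                         fix_topology=True, link_branch_lengths=True, sample_every=1)
        est = stepping_stone(m, model, cfg, n_steps=1, per_step_generations=800)
        assert np.isfinite(est.log_ml)
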