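"""Ancestral reconstruction: MPR sets and Mk1 marginals vs enumeration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from morphophylo.ancestral import (
    clade_ancestor_report,
    likelihood_ancestral_states,
    parsimony_ancestral_states,
)
from morphophylo.likelihood import mk_transition_probability
from morphophylo.matrix import CharacterMatrix
from morphophylo.trees import PhyloTree

from conftest import random_matrix


def brute_force_mpr(tree, matrix, char):
    """Union of internal-state assignments over all minimum-length labelings."""
    meta = matrix.char_meta[char]
    k = meta.n_states
    nodes = list(tree.postorder())
    internals = [nd for nd in nodes if not nd.is_leaf]
    best, sets = None, {}

    def cost(a, b):
        return abs(a - b) if meta.ordered else int(a != b)

    for states in itertools.product(range(k), repeat=len(internals)):
        sm = {id(nd): s for nd, s in zip(internals, states)}
        tot = 0
        for nd in nodes:
            if nd.parent is None:
                continue
            up = sm[id(nd.parent)]
            if nd.is_leaf:
                tot += min(cost(s, up) for s in matrix.state_set(nd.label, char))
            else:
                tot += cost(sm[id(nd)], up)
        if best is None or tot < best:
            best = tot
            sets = {id(nd): set() for nd in internals}
        if tot == best:
            for nd in internals:
                sets[id(nd)].add(sm[id(nd)])
    return {key: frozenset(v) for key, v in sets.items()}


class TestParsimonyMPR:
    def test_uniform_tips_give_uniform_ancestors(self):
        m = CharacterMatrix.from_rows(list("ABCD"), [[1]] * 4)
        t = PhyloTree.from_newick("((A,B),(C,D));")
        rec = parsimony_ancestral_states(t, m, 0)
        for nd in t.postorder():
            if not nd.is_leaf:
                assert rec.states_of(nd) == frozenset([1])

    @pytest.mark.parametrize("ordered", [False, True])
    def test_matches_bruteforce_union(self, ordered):
        rng = np.random.default_rng(47)
        t = PhyloTree.from_newick("((A,B),((C,D),(E,F)));")
        for _ in range(50):
            m = random_matrix(rng, 6, 1, k_max=4, missing_p=0.15)
            if ordered:
                m.char_meta[0].ordered = True
            rec = parsimony_ancestral_states(t, m, 0)
            oracle = brute_force_mpr(t, m, 0)
            for nd in t.postorder():
                if not nd.is_leaf:
                    assert rec.states_of(nd) == oracle[id(nd)]

    def test_polytomy_handled_as_hard(self):
        m = CharacterMatrix.from_rows(list("ABCDE"), [[0], [0], [1], [1], [1]])
        t = PhyloTree.from_newick("(A,B,(C,D,E));")
        rec = parsimony_ancestral_states(t, m, 0)
        inner = [nd for nd in t.postorder() if not nd.is_leaf and nd.parent][0]
        assert rec.states_of(inner) == frozenset([1])

    def test_leaf_sets_respect_observations(self):
        m = CharacterMatrix.from_rows(list("ABCD"), [[0], [{0, 1}], [1], [1]])
        t = PhyloTree.from_newick("((A,B),(C,D));")
        rec = parsimony_ancestral_states(t, m, 0)
        leafB = next(nd for nd in t.postorder() if nd.label == "B")
        assert rec.states_of(leafB) <= frozenset([0, 1])


class TestMk1Marginals:
    def enumeration_marginals(self, tree, leafstate, k, rate):
        nodes = list(tree.postorder())
        internals = [nd for nd in nodes if not nd.is_leaf]
        probs = {id(nd): np.zeros(k) for nd in internals}
        tot = 0.0
        for states in itertools.product(range(k), repeat=len(internals)):
            sm = {id(nd): s for nd, s in zip(internals, states)}
            p = 1.0 / k
            for nd in nodes:
                if nd.parent is None:
                    continue
                P = mk_transition_probability(k, nd.length, rate)
                s = sm[id(nd)] if not nd.is_leaf else None
                if nd.is_leaf:
                    p *= sum(P[sm[id(nd.parent)], x] for x in leafstate[nd.label])
                else:
                    p *= P[sm[id(nd.parent)], s]
            tot += p
            for nd in internals:
                probs[id(nd)][sm[id(nd)]] += p
        return {key: v / tot for key, v in probs.items()}

    def test_matches_enumeration_with_ambiguity(self):
        t = PhyloTree.from_newick("((A:0.2,B:0.4):0.3,(C:0.1,D:0.5):0.2);")
        m = CharacterMatrix.from_rows(list("ABCD"), [[0], [{0, 1}], [1], ["?"]])
        rec = likelihood_ancestral_states(t, m, 0, rate=0.8)
        leafstate = {lab: m.state_set(lab, 0) for lab in "ABCD"}
        oracle = self.enumeration_marginals(t, leafstate, 2, 0.8)
        for nd in t.postorder():
            if not nd.is_leaf:
                assert np.allclose(rec.states_of(nd), oracle[id(nd)], atol=1e-12)

    def test_root_placement_invariance(self):
        a = PhyloTree.from_newick("((A:0.2,B:0.4):0.3,(C:0.1,D:0.5):0.2);")
        b = PhyloTree.from_newick("(((C:0.1,D:0.5):0.5,A:0.2):0.0,B:0.4);")
        m = CharacterMatrix.from_rows(list("ABCD"), [[0], [1], [1], [0]])
        ra = likelihood_ancestral_states(a, m, 0, rate=1.1)
        rb = likelihood_ancestral_states(b, m, 0, rate=1.1)
        # compare marginals at the node above the CD cherry in both trees
        nd_a = a.mrca(["C", "D"])
        nd_b = b.mrca(["C", "D"])
        assert np.allclose(ra.states_of(nd_a), rb.states_of(nd_b), atol=1e-8)

    def test_zero_branch_star_consistent_tips(self):
        t = PhyloTree.from_newick("(A:0,B:0,C:0);")
        m = CharacterMatrix.from_rows(list("ABC"), [[0]] * 3, n_states=2)
        rec = likelihood_ancestral_states(t, m, 0, rate=1.0)
        assert rec.states_of(t.root)[0] == pytest.approx(1.0)

    def test_short_branches_approach_parsimony_reconstruction(self):
        # tip states chosen so the MPR is unique at every internal node
        newick = "((A:%g,B:%g):%g,(C:%g,D:%g):%g);"
        m = CharacterMatrix.from_rows(list("ABCD"), [[0], [0], [0], [1]])
        mpr = parsimony_ancestral_states(
            PhyloTree.from_newick(newick % ((0.01,) * 6)), m, 0
        )
        rec = likelihood_ancestral_states(
            PhyloTree.from_newick(newick % ((0.01,) * 6)), m, 0, rate=1.0
        )
        for nd_m, nd_l in zip(mpr.tree.postorder(), rec.tree.postorder()):
            if nd_m.is_leaf:
                continue
            (state,) = mpr.states_of(nd_m)
            assert rec.states_of(nd_l)[state] > 0.95

    def test_rate_is_fitted_when_not_given(self):
        t = PhyloTree.from_newick("((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2);")
        m = CharacterMatrix.from_rows(list("ABCD"), [[0], [0], [1], [1]])
        rec = likelihood_ancestral_states(t, m, 0)
        assert rec.rate_estimate > 0
        marg = rec.states_of(t.root)
        assert marg.sum() == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_character_flagged(self):
        t = PhyloTree.from_newick("((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2);")
        m = CharacterMatrix.from_rows(list("ABCD"), [[0], [0], ["?"], [0]], n_states=2)
        rec = likelihood_ancestral_states(t, m, 0)
        assert rec.degenerate


class TestCladeReport:
    def fixture(self):
        t = PhyloTree.from_newick(
            "(((A:0.1,B:0.1):0.1,C:0.2):0.1,(D:0.15,E:0.15):0.1);"
        )
        m = CharacterMatrix.from_rows(list("ABCDE"), [[1], [1], [0], [0], [0]])
        return t, m

    def test_monophyletic_clade_reports_mrca_values(self):
        t, m = self.fixture()
        rec = likelihood_ancestral_states(t, m, 0, rate=1.0)
        rep = clade_ancestor_report(rec, {"AB": ["A", "B"], "DE": ["D", "E"]})
        assert list(rep["status"]) == ["ok", "ok"]
        ab = rep[rep.clade == "AB"].iloc[0]
        direct = rec.states_of(t.mrca(["A", "B"]))
        assert ab["P(state 1)"] == pytest.approx(float(direct[1]), abs=1e-4)

    def test_whole_taxon_set_reports_root(self):
        t, m = self.fixture()
        rec = likelihood_ancestral_states(t, m, 0, rate=1.0)
        rep = clade_ancestor_report(rec, {"all": list("ABCDE")})
        root_vals = rec.states_of(t.root)
        assert rep.iloc[0]["P(state 0)"] == pytest.approx(float(root_vals[0]), abs=1e-4)

    def test_non_monophyletic_clade_flagged_without_numbers(self):
        t, m = self.fixture()
        rec = likelihood_ancestral_states(t, m, 0, rate=1.0)
        rep = clade_ancestor_report(rec, {"AD": ["A", "D"]})
        assert rep.iloc[0]["status"] == "not monophyletic"
        assert "P(state 0)" not in rep.columns or pd.isna(rep.iloc[0]["P(state 0)"])

    def test_parsimony_report_states(self):
        t, m = self.fixture()
        rec = parsimony_ancestral_states(t, m, 0)
        rep = clade_ancestor_report(rec, {"AB": ["A", "B"]})
        assert rep.iloc[0]["states"] == "1"
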