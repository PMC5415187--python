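"""Shared brute-force oracles, independent of the implementations they check.

All three enumerate internal-node state assignments explicitly, so they are
exponential in tree size and only used on <= 7-taxon instances.
"""

import itertools
import math

import numpy as np

from morphophylo.likelihood import mk_transition_probability


def _cost(meta):
    if meta.ordered:
        return lambda a, b: abs(a - b)
    return lambda a, b: int(a != b)


def brute_force_char_steps(tree, matrix, char):
    meta = matrix.char_meta[char]
    cost = _cost(meta)
    nodes = list(tree.postorder())
    internals = [nd for nd in nodes if not nd.is_leaf]
    best = None
    for states in itertools.product(range(meta.n_states), repeat=len(internals)):
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
        best = tot if best is None else min(best, tot)
    return best


def brute_force_mpr_sets(tree, matrix, char):
    meta = matrix.char_meta[char]
    cost = _cost(meta)
    nodes = list(tree.postorder())
    internals = [nd for nd in nodes if not nd.is_leaf]
    best, sets = None, {}
    for states in itertools.product(range(meta.n_states), repeat=len(internals)):
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


def enumeration_loglik(tree, matrix, model):
    """Per-character log-likelihood by summing over internal assignments."""
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
                        p *= sum(Ps[id(nd)][up, s] for s in matrix.state_set(nd.label, c))
                    else:
                        p *= Ps[id(nd)][up, sm[id(nd)]]
                site += p
        out.append(math.log(site / len(rates)))
    return np.array(out)
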