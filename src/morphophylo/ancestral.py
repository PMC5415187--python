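"""Ancestral-state reconstruction: parsimony MPR sets and Mk1 marginals.

Parsimony reconstruction returns, for every internal node, the full set of
states that occur in at least one most-parsimonious labelling (MPR), via a
Sankoff down-pass plus an up-pass that scores the remainder of the tree for
each candidate state.  Ordered characters use |i-j| step costs; polytomies
are treated as hard.

Likelihood reconstruction follows the one-parameter Mk ("Mk1") convention of
character-mapping tools: a single rate is fitted by maximum likelihood for
the character on the given tree (branch lengths fixed), and marginal
posterior state probabilities at each node are computed by re-rooted pruning
with flat (1/k) root frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .likelihood import mk_transition_probability
from .matrix import CharacterMatrix
from .parsimony import _step_matrix
from .trees import Node, PhyloTree

_INF = float(1 << 40)


@dataclass
class AncestralReconstruction:
    character: int
    tree: PhyloTree
    method: str  # "parsimony_mpr" | "likelihood_mk1"
    node_states: dict[int, object]  # id(node) -> frozenset | np.ndarray
    rate_estimate: float | None = None
    degenerate: bool = False

    def states_of(self, node: Node):
        return self.node_states[id(node)]


def _char_arrays(matrix: CharacterMatrix, char: int):
    meta = matrix.char_meta[char]
    k = meta.n_states
    masks = matrix.cells[:, char]
    tips = ((masks[:, None] >> np.arange(k)[None, :]) & 1).astype(float)
    return k, meta.ordered, tips


def parsimony_ancestral_states(
    tree: PhyloTree, matrix: CharacterMatrix, char: int
) -> AncestralReconstruction:
    """Full MPR state sets per node (down-pass + up-pass Sankoff)."""
    k, ordered, tips = _char_arrays(matrix, char)
    step = _step_matrix(k, ordered).astype(float)
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    nodes = list(tree.postorder())
    down: dict[int, np.ndarray] = {}
    for nd in nodes:
        if nd.is_leaf:
            down[id(nd)] = np.where(tips[taxon_row[nd.label]] > 0, 0.0, _INF)
        else:
            acc = np.zeros(k)
            for c in nd.children:
                acc += (down[id(c)][None, :] + step).min(axis=1)
            down[id(nd)] = np.minimum(acc, _INF)
    up: dict[int, np.ndarray] = {id(tree.root): np.zeros(k)}
    for nd in tree.preorder():
        for c in nd.children:
            # cost of everything outside c, as a function of c's state
            sib_cost = np.zeros(k)  # function of nd's state
            for s in nd.children:
                if s is not c:
                    sib_cost += (down[id(s)][None, :] + step).min(axis=1)
            total_at_nd = up[id(nd)] + sib_cost  # function of nd's state
            up[id(c)] = (total_at_nd[:, None] + step).min(axis=0)
    best = float(down[id(tree.root)].min())
    out: dict[int, object] = {}
    for nd in nodes:
        tot = down[id(nd)] + up[id(nd)]
        states = frozenset(int(s) for s in range(k) if tot[s] <= best + 1e-9)
        out[id(nd)] = states
    return AncestralReconstruction(char, tree, "parsimony_mpr", out)


def likelihood_ancestral_states(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    char: int,
    rate: float | None = None,
) -> AncestralReconstruction:
    """Marginal Mk1 state probabilities for one character at every node.

    The single rate is fitted by maximizing the character's likelihood on the
    given tree unless supplied.  Marginals are obtained by re-rooting the
    pruning at each node, which is exact for the reversible Mk chain.
    """
    k, _, tips = _char_arrays(matrix, char)
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    attested = {
        s
        for i in range(matrix.n_taxa)
        for s in range(k)
        if tips[i, s] > 0 and not matrix.is_missing(i, char)
    }
    degenerate = len(attested) < 2
    nodes = list(tree.postorder())
    for nd in nodes:
        if nd is not tree.root and (nd.length is None or nd.length < 0):
            raise ValueError("likelihood reconstruction needs branch lengths")

    # adjacency with lengths, ids = postorder index
    index = {id(nd): i for i, nd in enumerate(nodes)}
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(nodes))}
    for nd in nodes:
        if nd.parent is not None:
            i, j = index[id(nd)], index[id(nd.parent)]
            t = max(nd.length or 0.0, 0.0)
            adj[i].append((j, t))
            adj[j].append((i, t))
    leaf_partial = {
        index[id(nd)]: tips[taxon_row[nd.label]] for nd in nodes if nd.is_leaf
    }

    def message(src: int, dst: int, t: float, r: float, memo) -> np.ndarray:
        """Partial likelihood of the subtree behind src, seen across edge
        (src -> dst), as a function of dst's state."""
        key = (src, dst)
        if key in memo:
            return memo[key]
        if src in leaf_partial and len(adj[src]) == 1:
            x = leaf_partial[src]
        else:
            x = np.ones(k)
            if src in leaf_partial:
                x = leaf_partial[src].copy()
            for nb, tt in adj[src]:
                if nb != dst:
                    x = x * message(nb, src, tt, r, memo)
        P = mk_transition_probability(k, t, r)
        out = P @ x
        memo[key] = out
        return out

    def root_partial(v: int, r: float, memo) -> np.ndarray:
        x = np.ones(k)
        if v in leaf_partial:
            x = leaf_partial[v].copy()
        for nb, tt in adj[v]:
            x = x * message(nb, v, tt, r, memo)
        return x

    def loglik(r: float) -> float:
        memo: dict = {}
        x = root_partial(len(nodes) - 1, r, memo)
        s = x.sum() / k
        return math.log(s) if s > 0 else -math.inf

    if rate is None:
        if degenerate:
            rate = 1e-8
        else:
            res = optimize.minimize_scalar(
                lambda r: -loglik(r), bounds=(1e-6, 100.0), method="bounded",
                options={"xatol": 1e-8},
            )
            rate = float(res.x)
    memo: dict = {}
    out: dict[int, object] = {}
    for nd in nodes:
        x = root_partial(index[id(nd)], rate, memo)
        tot = x.sum()
        if tot <= 0:
            raise ValueError(f"zero likelihood at node for character {char + 1}")
        out[id(nd)] = x / tot
    return AncestralReconstruction(
        char, tree, "likelihood_mk1", out, rate_estimate=rate, degenerate=degenerate
    )


def clade_ancestor_report(
    recon: AncestralReconstruction, clades: dict[str, list[str]]
) -> pd.DataFrame:
    """State probabilities/sets at the MRCA of each named clade.

    A clade not present as a monophyletic group on the tree is flagged, with
    no state values, as is a degenerate (effectively invariant) character.
    """
    tree = recon.tree
    labels = set(tree.leaf_labels)
    rows = []
    k = (
        len(next(iter(recon.node_states.values())))
        if recon.method == "likelihood_mk1"
        else None
    )
    for name, members in clades.items():
        want = set(members)
        row: dict = {"clade": name}
        if not want <= labels:
            row["status"] = "taxa missing from tree"
            rows.append(row)
            continue
        node = tree.mrca(want)
        below = {lf.label for lf in PhyloTree(node, True).leaves()}
        if below != want and want != labels:
            row["status"] = "not monophyletic"
            rows.append(row)
            continue
        if recon.degenerate:
            row["status"] = "ambiguous (invariant character)"
            rows.append(row)
            continue
        row["status"] = "ok"
        st = recon.states_of(node)
        if recon.method == "parsimony_mpr":
            row["states"] = "/".join(str(s) for s in sorted(st))
        else:
            for s, p in enumerate(st):
                row[f"P(state {s})"] = round(float(p), 4)
        rows.append(row)
    return pd.DataFrame(rows)
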