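"""Parsimony: tree length, implied weighting, heuristic TBR search, consensus.

Character fit is computed by a vectorized Sankoff dynamic program with the
step matrix of the character type (unit steps for unordered/non-additive
characters, ``|i-j|`` for ordered/additive ones).  On bifurcating trees this
reduces exactly to Fitch counting for unordered characters and to the Farris
interval algorithm for ordered ones, and it remains exact on polytomies
(treated as hard) and for polymorphic/missing cells, which enter as the set
of permitted tip states minimized over.

Searches operate on an unrooted adjacency representation: random-addition
Wagner starting trees followed by tree-bisection-reconnection (TBR)
hill-climbing, with an SPR-restricted mode for larger matrices.  Equally
optimal trees are pooled, deduplicated on unrooted topology, and returned as
a :class:`TreeSet`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .matrix import CharacterMatrix
from .trees import Node, PhyloTree
from .trees import strict_consensus, majority_consensus  # noqa: F401  (re-export)

_INF = np.int64(1) << 40


# -- score containers ---------------------------------------------------


@dataclass
class ParsimonyScore:
    total_steps: int
    per_char_steps: np.ndarray
    ci: float | None = None
    ri: float | None = None
    fit: float | None = None
    concave_fit: float | None = None

    def __repr__(self):  # pragma: no cover
        parts = [f"steps={self.total_steps}"]
        if self.fit is not None:
            parts.append(f"fit={self.fit:.5f}")
        return f"<ParsimonyScore {' '.join(parts)}>"


@dataclass
class SearchConfig:
    n_replicates: int = 100
    n_iterations: int = 100
    hold: int = 10000
    seed: int = 0
    objective: str = "equal_weights"  # or "implied_weights"
    k: float = 3.0
    move_set: str = "tbr"  # "tbr" or "spr"
    plateau_limit: int = 200

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.k <= 0:
            raise ValueError("concavity constant k must be > 0")
        if self.objective not in ("equal_weights", "implied_weights"):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class TreeSet:
    trees: list[PhyloTree]
    score: ParsimonyScore
    truncated: bool = False


# -- per-character bounds ----------------------------------------------


def min_and_max_steps(matrix: CharacterMatrix, char: int) -> tuple[int, int]:
    """Minimum conceivable steps and star-tree (maximum) steps for a character.

    The minimum is over all trees and all resolutions of ambiguous cells; the
    maximum is the cost on the completely unresolved tree, with ambiguous
    cells assigned their best state relative to the optimal median.
    """
    meta = matrix.char_meta[char]
    k = meta.n_states
    full = (1 << k) - 1
    cells = [int(m) for m in matrix.cells[:, char] if int(m) != full]
    if not cells or k == 1:
        return 0, 0
    states = range(k)
    if meta.ordered:
        lo = max(min(s for s in states if m >> s & 1) for m in cells)
        hi = min(max(s for s in states if m >> s & 1) for m in cells)
        m_c = max(0, lo - hi)
    else:
        # smallest set of states hitting every cell, minus one
        attested = [s for s in states if any(m >> s & 1 for m in cells)]
        m_c = len(attested) - 1
        for size in range(1, len(attested) + 1):
            done = False
            for combo in itertools.combinations(attested, size):
                cmask = sum(1 << s for s in combo)
                if all(m & cmask for m in cells):
                    m_c = size - 1
                    done = True
                    break
            if done:
                break
    step = _step_matrix(k, meta.ordered)
    g_c = min(
        sum(min(int(step[x, s]) for x in states if m >> x & 1) for m in cells)
        for s in states
    )
    return int(m_c), int(g_c)


def _step_matrix(k: int, ordered: bool) -> np.ndarray:
    idx = np.arange(k)
    if ordered:
        return np.abs(idx[:, None] - idx[None, :]).astype(np.int64)
    return (idx[:, None] != idx[None, :]).astype(np.int64)


# -- scoring engine ------------------------------------------------------


@njit(cache=False)
def _sankoff_kernel(children_flat, child_off, leaf_taxon, tip, step):
    """Per-character minimum steps by the Sankoff DP (postorder, root last)."""
    N = child_off.shape[0] - 1
    C = tip.shape[1]
    k = tip.shape[2]
    INF = np.int64(1) << 40
    cost = np.empty((N, C, k), np.int64)
    for v in range(N):
        s0, s1 = child_off[v], child_off[v + 1]
        if s1 == s0:
            t = leaf_taxon[v]
            for c in range(C):
                for a in range(k):
                    cost[v, c, a] = tip[t, c, a]
        else:
            for c in range(C):
                for a in range(k):
                    cost[v, c, a] = 0
            for ci in range(s0, s1):
                w = children_flat[ci]
                for c in range(C):
                    for a in range(k):
                        best = INF
                        for b in range(k):
                            val = cost[w, c, b] + step[a, b]
                            if val < best:
                                best = val
                        acc = cost[v, c, a] + best
                        cost[v, c, a] = acc if acc < INF else INF
    out = np.empty(C, np.int64)
    for c in range(C):
        best = cost[N - 1, c, 0]
        for a in range(1, k):
            if cost[N - 1, c, a] < best:
                best = cost[N - 1, c, a]
        out[c] = best
    return out


def _flatten_children(postorder_children: list[list[int]]):
    off = np.zeros(len(postorder_children) + 1, dtype=np.int64)
    flat = []
    for i, ch in enumerate(postorder_children):
        flat.extend(ch)
        off[i + 1] = len(flat)
    return np.asarray(flat, dtype=np.int64), off


class ParsimonyEngine:
    """Caches tip cost arrays so many trees can be scored against one matrix."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.n_characters = matrix.n_characters
        self.groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        by_type: dict[tuple[int, bool], list[int]] = {}
        for c, meta in enumerate(matrix.char_meta):
            if meta.active and meta.n_states >= 2:
                by_type.setdefault((meta.n_states, meta.ordered), []).append(c)
        for (k, ordered), chars in sorted(by_type.items()):
            step = _step_matrix(k, ordered)
            masks = matrix.cells[:, chars]  # (n_taxa, C_g)
            tip = np.where(
                (masks[:, :, None] >> np.arange(k)[None, None, :]) & 1, 0, _INF
            ).astype(np.int64)
            self.groups.append((np.asarray(chars), step, tip))
        mm = [min_and_max_steps(matrix, c) for c in range(matrix.n_characters)]
        self.min_steps = np.array([m for m, _ in mm], dtype=np.int64)
        self.max_steps = np.array([g for _, g in mm], dtype=np.int64)

    # tree structure -> per-character steps
    def per_char_steps_struct(
        self, postorder_children: list[list[int]], leaf_taxon: np.ndarray
    ) -> np.ndarray:
        flat, off = _flatten_children(postorder_children)
        out = np.zeros(self.n_characters, dtype=np.int64)
        for chars, step, tip in self.groups:
            out[chars] = _sankoff_kernel(flat, off, leaf_taxon, tip, step)
        return out

    def per_char_steps(self, tree: PhyloTree) -> np.ndarray:
        children, leaf_taxon = _tree_struct(tree, self.matrix)
        return self.per_char_steps_struct(children, leaf_taxon)

    def score(self, tree: PhyloTree, k: float | None = None) -> ParsimonyScore:
        steps = self.per_char_steps(tree)
        return self.build_score(steps, k)

    def build_score(self, steps: np.ndarray, k: float | None = None) -> ParsimonyScore:
        score = ParsimonyScore(int(steps.sum()), steps)
        score.ci, score.ri = ensemble_ci_ri_from_vectors(
            steps, self.min_steps, self.max_steps
        )
        if k is not None:
            h = np.maximum(steps - self.min_steps, 0).astype(float)
            score.fit = float(np.sum(h / (h + k)))
            active = sum(len(chars) for chars, _, _ in self.groups)
            score.concave_fit = active - score.fit
        return score

    def objective_struct(
        self,
        postorder_children: list[list[int]],
        leaf_taxon: np.ndarray,
        objective: str,
        k: float,
    ) -> float:
        steps = self.per_char_steps_struct(postorder_children, leaf_taxon)
        if objective == "equal_weights":
            return float(steps.sum())
        h = np.maximum(steps - self.min_steps, 0).astype(float)
        return float(np.sum(h / (h + k)))


def _tree_struct(
    tree: PhyloTree, matrix: CharacterMatrix
) -> tuple[list[list[int]], np.ndarray]:
    """Postorder children lists and leaf->taxon-row map (root last)."""
    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    nodes = list(tree.postorder())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    children = [[index[id(c)] for c in nd.children] for nd in nodes]
    leaf_taxon = np.zeros(len(nodes), dtype=np.int64)
    for i, nd in enumerate(nodes):
        if nd.is_leaf:
            if nd.label not in taxon_row:
                raise ValueError(f"leaf {nd.label!r} absent from matrix")
            leaf_taxon[i] = taxon_row[nd.label]
    return children, leaf_taxon


# -- public scoring operations ------------------------------------------


def character_steps(tree: PhyloTree, matrix: CharacterMatrix, char: int) -> int:
    return int(ParsimonyEngine(matrix).per_char_steps(tree)[char])


def tree_length(tree: PhyloTree, matrix: CharacterMatrix) -> ParsimonyScore:
    return ParsimonyEngine(matrix).score(tree)


def ensemble_ci_ri_from_vectors(
    steps: np.ndarray, min_steps: np.ndarray, max_steps: np.ndarray,
    informative_only: bool = False,
) -> tuple[float | None, float | None]:
    use = min_steps > 0
    if informative_only:
        use &= max_steps > min_steps
    s, m, g = steps[use].sum(), min_steps[use].sum(), max_steps[use].sum()
    ci = float(m / s) if s > 0 else None
    ri = float((g - s) / (g - m)) if g > m else None
    return ci, ri


def ensemble_ci_ri(
    score: ParsimonyScore, matrix: CharacterMatrix, informative_only: bool = False
) -> tuple[float | None, float | None]:
    """Ensemble consistency and retention indices, CI = Σm/Σs, RI = (Σg−Σs)/(Σg−Σm).

    Sums run over variable characters; autapomorphic (uninformative) ones are
    included by default, matching the convention of the parsimony program the
    printed values come from, with ``informative_only`` as the alternative.
    """
    mm = [min_and_max_steps(matrix, c) for c in range(matrix.n_characters)]
    m = np.array([a for a, _ in mm], dtype=np.int64)
    g = np.array([b for _, b in mm], dtype=np.int64)
    return ensemble_ci_ri_from_vectors(score.per_char_steps, m, g, informative_only)


def implied_weight_fit(
    tree: PhyloTree, matrix: CharacterMatrix, k: float = 3.0
) -> float:
    """Goloboff distortion F = Σ_c h_c/(h_c + k); 0 iff homoplasy-free. Minimized."""
    eng = ParsimonyEngine(matrix)
    return float(eng.score(tree, k=k).fit)


# -- unrooted adjacency trees for search ---------------------------------


class _AdjTree:
    """Unrooted binary tree: leaves 0..n-1 (matrix taxon rows), internals >= n."""

    __slots__ = ("adj", "next_id", "n_leaves")

    def __init__(self, adj: dict[int, list[int]], next_id: int, n_leaves: int):
        self.adj = adj
        self.next_id = next_id
        self.n_leaves = n_leaves

    def copy(self) -> "_AdjTree":
        return _AdjTree({k: list(v) for k, v in self.adj.items()}, self.next_id, self.n_leaves)

    def edges(self) -> list[tuple[int, int]]:
        return [(a, b) for a in self.adj for b in self.adj[a] if a < b]

    def struct(self) -> tuple[list[list[int]], np.ndarray]:
        root = max(self.adj)
        order: list[int] = []
        children: list[list[int]] = []
        stack = [(root, -1, False)]
        post_index: dict[int, int] = {}
        while stack:
            v, parent, seen = stack.pop()
            if seen:
                post_index[v] = len(order)
                order.append(v)
                children.append([post_index[w] for w in self.adj[v] if w != parent])
            else:
                stack.append((v, parent, True))
                for w in self.adj[v]:
                    if w != parent:
                        stack.append((w, v, False))
        leaf_taxon = np.array([v if v < self.n_leaves else 0 for v in order], dtype=np.int64)
        return children, leaf_taxon

    def to_phylo(self, taxa: Sequence[str]) -> PhyloTree:
        root_id = max(self.adj)

        def build(v: int, parent: int) -> Node:
            nd = Node(taxa[v] if v < self.n_leaves else None)
            for w in self.adj[v]:
                if w != parent:
                    nd.add_child(build(w, v))
            return nd

        return PhyloTree(build(root_id, -1), rooted=False)

    def topology_key(self) -> frozenset:
        # splits as frozensets of leaf ids on the side without leaf 0
        all_leaves = frozenset(range(self.n_leaves))
        splits = set()
        root = max(self.adj)
        below: dict[tuple[int, int], frozenset] = {}
        stack = [(root, -1, False)]
        while stack:
            v, parent, seen = stack.pop()
            if seen:
                if v < self.n_leaves:
                    below[(v, parent)] = frozenset([v])
                else:
                    below[(v, parent)] = frozenset().union(
                        *(below[(w, v)] for w in self.adj[v] if w != parent)
                    )
                if parent != -1:
                    side = below[(v, parent)]
                    if 0 in side:
                        side = all_leaves - side
                    if 2 <= len(side) <= self.n_leaves - 2:
                        splits.add(side)
            else:
                stack.append((v, parent, True))
                for w in self.adj[v]:
                    if w != parent:
                        stack.append((w, v, False))
        return frozenset(splits)


def _initial_triple(t0: int, t1: int, t2: int, n: int) -> _AdjTree:
    hub = n
    adj = {t0: [hub], t1: [hub], t2: [hub], hub: [t0, t1, t2]}
    return _AdjTree(adj, n + 1, n)


def _insert_leaf(tree: _AdjTree, leaf: int, edge: tuple[int, int]) -> None:
    a, b = edge
    w = tree.next_id
    tree.next_id += 1
    tree.adj[a].remove(b)
    tree.adj[b].remove(a)
    tree.adj[a].append(w)
    tree.adj[b].append(w)
    tree.adj[w] = [a, b, leaf]
    tree.adj[leaf] = [w]


def _bisect(tree: _AdjTree, u: int, v: int):
    """Split on edge (u, v); returns (nodes_u_side, nodes_v_side) after removal."""
    adj = tree.adj
    adj[u].remove(v)
    adj[v].remove(u)

    def comp(start: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    return comp(u), comp(v)


def _suppress(tree: _AdjTree, v: int) -> tuple[int, int] | None:
    """Remove a degree-2 node, joining its neighbours; returns the new edge."""
    adj = tree.adj
    if len(adj[v]) != 2:
        return None
    x, y = adj[v]
    adj[x].remove(v)
    adj[y].remove(v)
    adj[x].append(y)
    adj[y].append(x)
    del adj[v]
    return (x, y) if x < y else (y, x)


def _reattach(tree: _AdjTree, joint: int, edge_or_node):
    adj = tree.adj
    if isinstance(edge_or_node, tuple):
        a, b = edge_or_node
        adj[a].remove(b)
        adj[b].remove(a)
        adj[a].append(joint)
        adj[b].append(joint)
        adj.setdefault(joint, []).extend([a, b])
    else:
        adj.setdefault(joint, []).append(edge_or_node)
        adj[edge_or_node].append(joint)


def _neighbors(tree: _AdjTree, move_set: str = "tbr") -> Iterable[_AdjTree]:
    """TBR rearrangements: bisect an edge, reconnect any edge pair across the
    two subtrees.  ``spr`` restricts one side's attachment to where it was cut
    (classic subtree pruning-regrafting), shrinking the neighbourhood from
    O(n^3) to O(n^2) for larger matrices.
    """
    for u, v in tree.edges():
        base = tree.copy()
        comp_u, comp_v = _bisect(base, u, v)
        # suppress the degree-2 stumps; remember the edge each one occupied
        if len(comp_u) > 1:
            comp_u.discard(u)
            cut_u = _suppress(base, u)
        else:
            cut_u = u  # single leaf: the attachment *is* the node
        if len(comp_v) > 1:
            comp_v.discard(v)
            cut_v = _suppress(base, v)
        else:
            cut_v = v
        edges_u = [e for e in base.edges() if e[0] in comp_u] or [next(iter(comp_u))]
        edges_v = [e for e in base.edges() if e[0] in comp_v] or [next(iter(comp_v))]
        if move_set == "spr":
            pairs = {(eu, cut_v) for eu in edges_u} | {(cut_u, ev) for ev in edges_v}
        else:
            pairs = {(eu, ev) for eu in edges_u for ev in edges_v}
        for eu, ev in pairs:
            cand = base.copy()
            if isinstance(eu, tuple):
                _subdivide_with(cand, eu, u)
                end_u = u
            else:
                end_u = eu
            if isinstance(ev, tuple):
                _subdivide_with(cand, ev, v)
                end_v = v
            else:
                end_v = ev
            cand.adj[end_u].append(end_v)
            cand.adj[end_v].append(end_u)
            yield cand


def _subdivide_with(tree: _AdjTree, edge: tuple[int, int], node: int) -> None:
    a, b = edge
    adj = tree.adj
    adj[a].remove(b)
    adj[b].remove(a)
    adj[a].append(node)
    adj[b].append(node)
    adj[node] = [a, b]


# -- heuristic search ----------------------------------------------------


def heuristic_search(matrix: CharacterMatrix, config: SearchConfig) -> TreeSet:
    """Random-addition Wagner trees + TBR hill climbing under the objective.

    Deterministic given ``config.seed``; pools and deduplicates all equally
    optimal trees found across replicates (up to ``config.hold``).
    """
    if matrix.n_taxa < 4:
        raise ValueError("search requires at least 4 taxa")
    eng = ParsimonyEngine(matrix)
    rng = np.random.default_rng(config.seed)
    k = config.k
    obj = config.objective

    def value(t: _AdjTree) -> float:
        ch, lt = t.struct()
        return eng.objective_struct(ch, lt, obj, k)

    best_val: float | None = None
    pool: dict[frozenset, _AdjTree] = {}
    truncated = False

    for _ in range(config.n_replicates):
        order = rng.permutation(matrix.n_taxa)
        tree = _initial_triple(int(order[0]), int(order[1]), int(order[2]), matrix.n_taxa)
        for leaf in order[3:]:
            cands = []
            for edge in tree.edges():
                cand = tree.copy()
                _insert_leaf(cand, int(leaf), edge)
                cands.append((value(cand), cand))
            lo = min(v for v, _ in cands)
            ties = [c for v, c in cands if v <= lo + 1e-9]
            tree = ties[rng.integers(len(ties))]
        cur_val = value(tree)

        # hill climb
        for _ in range(config.n_iterations):
            improved = False
            best_nb, best_nb_val = None, cur_val
            for nb in _neighbors(tree, config.move_set):
                v = value(nb)
                if v < best_nb_val - 1e-9:
                    best_nb, best_nb_val = nb, v
            if best_nb is not None:
                tree, cur_val = best_nb, best_nb_val
                improved = True
            if not improved:
                break

        if best_val is None or cur_val < best_val - 1e-9:
            best_val = cur_val
            pool = {tree.topology_key(): tree}
        elif cur_val <= best_val + 1e-9:
            pool.setdefault(tree.topology_key(), tree)

    # plateau sweep: collect equally optimal neighbours of pooled optima
    frontier = list(pool.values())
    processed = 0
    while frontier and processed < config.plateau_limit and len(pool) < config.hold:
        t = frontier.pop()
        processed += 1
        for nb in _neighbors(t, config.move_set):
            key = nb.topology_key()
            if key in pool:
                continue
            if value(nb) <= best_val + 1e-9:
                if len(pool) >= config.hold:
                    truncated = True
                    break
                pool[key] = nb
                frontier.append(nb)

    trees = [t.to_phylo(matrix.taxa) for t in pool.values()]
    steps = eng.per_char_steps(trees[0])
    score = eng.build_score(steps, k=k if obj == "implied_weights" else None)
    if obj == "implied_weights" and score.fit is None:
        score.fit = best_val
    return TreeSet(trees=trees, score=score, truncated=truncated)


def exhaustive_search(
    matrix: CharacterMatrix, objective: str = "equal_weights", k: float = 3.0
) -> TreeSet:
    """Score every unrooted binary topology (for <= ~9 taxa); oracle-grade."""
    eng = ParsimonyEngine(matrix)
    n = matrix.n_taxa
    best_val, pool = None, []
    for tree in _all_topologies(n):
        ch, lt = tree.struct()
        v = eng.objective_struct(ch, lt, objective, k)
        if best_val is None or v < best_val - 1e-9:
            best_val, pool = v, [tree]
        elif v <= best_val + 1e-9:
            pool.append(tree)
    trees = [t.to_phylo(matrix.taxa) for t in pool]
    steps = eng.per_char_steps(trees[0])
    score = eng.build_score(steps, k=k if objective == "implied_weights" else None)
    return TreeSet(trees=trees, score=score)


def _all_topologies(n: int) -> Iterable[_AdjTree]:
    def rec(tree: _AdjTree, leaf: int):
        if leaf == n:
            yield tree
            return
        for edge in tree.edges():
            cand = tree.copy()
            _insert_leaf(cand, leaf, edge)
            yield from rec(cand, leaf + 1)

    yield from rec(_initial_triple(0, 1, 2, n), 3)
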