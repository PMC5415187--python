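"""Mk-model likelihood for discrete morphological characters.

The substitution model is Lewis's Mk: a k-state Jukes-Cantor generalization
with equal exchange rates and stationary frequencies 1/k, scaled so one unit
of branch length is one expected change.  Among-character rate variation is
modelled by G equal-probability discrete categories of a mean-one gamma or
lognormal distribution.  Because morphological matrices contain no invariant
characters, the likelihood can be conditioned on variability (the Mk(V)
ascertainment correction): each character's likelihood is divided by the
probability that a character evolved on the same tree is variable.

Characters are partitioned by their state count k; each partition has its own
Mk dimension and its own constant-pattern correction, sharing one rate law.

Transition probabilities have the closed form
``P_ii = 1/k + (k-1)/k * exp(-k r t/(k-1))`` and
``P_ij = (1 - exp(-k r t/(k-1)))/k``, so pruning messages reduce to
``(1-e)/k * sum(x) + e * x`` and no matrix exponentials are needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy import optimize, special, stats

from .matrix import CharacterMatrix
from .trees import Node, PhyloTree

BL_MIN, BL_MAX = 1e-8, 20.0
_LNL_TOL = 1e-6


@dataclass
class MkModelSpec:
    rate_law: str = "gamma"  # "equal" | "gamma" | "lognormal"
    shape: float = 1.0  # gamma alpha, or lognormal sigma
    n_categories: int = 8
    ascertainment: str = "variable_only"  # or "none"

    def __post_init__(self):
        if self.rate_law not in ("equal", "gamma", "lognormal"):
            raise ValueError(f"unknown rate law {self.rate_law!r}")
        if self.rate_law == "gamma" and self.shape <= 0:
            raise ValueError("gamma shape must be > 0")
        if self.rate_law == "lognormal" and self.shape < 0:
            raise ValueError("lognormal sigma must be >= 0")
        if self.ascertainment not in ("none", "variable_only"):
            raise ValueError(f"unknown ascertainment {self.ascertainment!r}")

    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        return discretize_rates(self.rate_law, self.shape, self.n_categories)


@dataclass
class LikelihoodResult:
    log_likelihood: float
    per_char_lnL: np.ndarray
    tree: PhyloTree
    shape: float | None = None
    model: MkModelSpec | None = None


def mk_transition_probability(k: int, t: float, r: float = 1.0) -> np.ndarray:
    """Mk transition matrix for a branch of t expected changes at rate r."""
    if k < 2:
        raise ValueError("Mk model needs at least 2 states")
    if t < 0 or r <= 0:
        raise ValueError("need t >= 0 and r > 0")
    e = math.exp(-k * r * t / (k - 1))
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * e)
    return P


def discretize_rates(law: str, shape: float, G: int) -> tuple[np.ndarray, np.ndarray]:
    """G equal-probability category rates with mean exactly one.

    Each category rate is the conditional mean of the mean-one distribution
    over its probability quantile slice (gamma with rate = shape; lognormal
    with location -sigma^2/2).
    """
    p = np.full(G, 1.0 / G)
    if law == "equal" or G == 1:
        return np.ones(1), np.full(1, 1.0)
    if law == "gamma":
        a = shape
        edges = special.gammaincinv(a, np.linspace(0, 1, G + 1)) / a
        # mean of gamma(a, rate=a) over [lo, hi] times G:
        upper = special.gammainc(a + 1, edges[1:] * a)
        lower = special.gammainc(a + 1, edges[:-1] * a)
        r = (upper - lower) * G
    elif law == "lognormal":
        s = shape
        if s == 0:
            return p, np.ones(G)
        mu = -0.5 * s * s
        q = np.linspace(0, 1, G + 1)
        z = stats.norm.ppf(q)
        # E[X; X in slice] for lognormal(mu, s) with overall mean 1
        upper = stats.norm.cdf(z[1:] - s)
        lower = stats.norm.cdf(z[:-1] - s)
        r = (upper - lower) * G
    else:
        raise ValueError(f"unknown rate law {law!r}")
    r = np.maximum(r, 1e-12)
    r = r / (p @ r)
    return p, r


# -- pruning evaluator ---------------------------------------------------


@njit(cache=False)
def _prune_kernel(flat, off, leaf_taxon, lengths, tips, rates, k):
    """Felsenstein pruning with per-node rescaling; postorder, root last.

    Returns per-character log-likelihoods; NaN marks a zero partial.
    """
    N = off.shape[0] - 1
    C = tips.shape[1]
    G = rates.shape[0]
    partial = np.empty((N, C, G, k))
    scale = np.zeros(C)
    for v in range(N):
        s0, s1 = off[v], off[v + 1]
        if s1 == s0:
            t = leaf_taxon[v]
            for c in range(C):
                for g in range(G):
                    for a in range(k):
                        partial[v, c, g, a] = tips[t, c, a]
            continue
        for c in range(C):
            for g in range(G):
                for a in range(k):
                    partial[v, c, g, a] = 1.0
        for ci in range(s0, s1):
            w = flat[ci]
            tl = lengths[w]
            for g in range(G):
                e = math.exp(-k * rates[g] * tl / (k - 1))
                q = (1.0 - e) / k
                for c in range(C):
                    S = 0.0
                    for a in range(k):
                        S += partial[w, c, g, a]
                    base = q * S
                    for a in range(k):
                        partial[v, c, g, a] *= base + e * partial[w, c, g, a]
        for c in range(C):
            m = 0.0
            for g in range(G):
                for a in range(k):
                    if partial[v, c, g, a] > m:
                        m = partial[v, c, g, a]
            if m <= 0.0:
                scale[c] = np.nan
            else:
                for g in range(G):
                    for a in range(k):
                        partial[v, c, g, a] /= m
                scale[c] += math.log(m)
    out = np.empty(C)
    for c in range(C):
        s = 0.0
        for g in range(G):
            for a in range(k):
                s += partial[N - 1, c, g, a]
        site = s / (k * G)
        out[c] = math.log(site) + scale[c] if site > 0 else np.nan
    return out


class _Partition:
    __slots__ = ("k", "chars", "tips")

    def __init__(self, k: int, chars: np.ndarray, tips: np.ndarray):
        self.k = k
        self.chars = chars
        self.tips = tips  # (n_taxa, C, k) float 0/1


class MkEvaluator:
    """Binds a matrix and model; scores any tree (with branch lengths) fast."""

    def __init__(self, matrix: CharacterMatrix, model: MkModelSpec):
        self.matrix = matrix
        self.model = model
        self.partitions: list[_Partition] = []
        by_k: dict[int, list[int]] = {}
        for c, meta in enumerate(matrix.char_meta):
            if not meta.active:
                continue
            full = (1 << meta.n_states) - 1
            col = matrix.cells[:, c]
            scored = col != full
            if not scored.any():
                continue  # all-missing: likelihood 1, contributes 0
            if model.ascertainment == "variable_only" and scored.all():
                attested = 0
                for m_ in col:
                    attested |= int(m_)
                if bin(attested).count("1") < 2:
                    # fully scored and invariant contradicts the conditioning;
                    # characters constant only through missingness are fine
                    raise ValueError(
                        f"character {c + 1} is invariant; the variable-only "
                        "ascertainment model excludes invariant characters"
                    )
            by_k.setdefault(meta.n_states, []).append(c)
        for k, chars in sorted(by_k.items()):
            masks = matrix.cells[:, chars]
            tips = (
                (masks[:, :, None] >> np.arange(k)[None, None, :]) & 1
            ).astype(float)
            self.partitions.append(_Partition(k, np.asarray(chars), tips))

    # tree structure helpers
    def struct(self, tree: PhyloTree):
        taxon_row = {t: i for i, t in enumerate(self.matrix.taxa)}
        nodes = list(tree.postorder())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children = [[index[id(c)] for c in nd.children] for nd in nodes]
        lengths = np.array(
            [nd.length if nd.length is not None else 0.0 for nd in nodes]
        )
        leaf_taxon = np.array(
            [taxon_row[nd.label] if nd.is_leaf else -1 for nd in nodes],
            dtype=np.int64,
        )
        if np.any(lengths[:-1] < 0):
            raise ValueError("negative branch length")
        return children, np.clip(lengths, 0.0, None), leaf_taxon, nodes

    def _prune(
        self,
        part_tips: np.ndarray,
        k: int,
        children: list[list[int]],
        lengths: np.ndarray,
        leaf_taxon: np.ndarray,
        rates: np.ndarray,
    ) -> np.ndarray:
        """Per-character log-likelihood given tip partials (n_taxa, C, k)."""
        from .parsimony import _flatten_children

        flat, off = _flatten_children(children)
        out = _prune_kernel(
            flat, off, leaf_taxon, np.asarray(lengths, float),
            np.ascontiguousarray(part_tips, dtype=np.float64),
            np.asarray(rates, float), k,
        )
        bad = ~np.isfinite(out)
        if np.any(bad):
            raise ValueError(
                "non-finite likelihood (zero partial) for characters "
                f"{np.nonzero(bad)[0].tolist()}"
            )
        return out

    def _constant_pattern_loglik(
        self,
        k: int,
        children: list[list[int]],
        lengths: np.ndarray,
        leaf_taxon: np.ndarray,
        rates: np.ndarray,
    ) -> np.ndarray:
        """Log-likelihood of each of the k constant patterns (all taxa scored)."""
        tips = np.broadcast_to(
            np.eye(k)[None, :, :], (self.matrix.n_taxa, k, k)
        ).copy()
        return self._prune(tips, k, children, lengths, leaf_taxon, rates)

    def per_char_loglik(
        self, tree: PhyloTree, shape: float | None = None
    ) -> np.ndarray:
        model = self.model if shape is None else replace(self.model, shape=shape)
        _, rates = model.category_rates()
        children, lengths, leaf_taxon, _ = self.struct(tree)
        out = np.zeros(self.matrix.n_characters)
        for part in self.partitions:
            lnl = self._prune(part.tips, part.k, children, lengths, leaf_taxon, rates)
            if model.ascertainment == "variable_only":
                const = self._constant_pattern_loglik(
                    part.k, children, lengths, leaf_taxon, rates
                )
                p_const = np.exp(const).sum()
                if p_const >= 1.0:
                    raise ValueError(
                        "ascertainment correction degenerate: P(constant) >= 1"
                    )
                lnl = lnl - math.log1p(-p_const)
            out[part.chars] = lnl
        return out

    def loglik(self, tree: PhyloTree, shape: float | None = None) -> float:
        return float(self.per_char_loglik(tree, shape).sum())


# -- public operations ---------------------------------------------------


def tree_log_likelihood(
    tree: PhyloTree, matrix: CharacterMatrix, model: MkModelSpec
) -> LikelihoodResult:
    """Felsenstein-pruning log-likelihood of a tree with branch lengths."""
    ev = MkEvaluator(matrix, model)
    per_char = ev.per_char_loglik(tree)
    return LikelihoodResult(float(per_char.sum()), per_char, tree, model.shape, model)


class _BranchProfiler:
    """Down/up partial caches for fast single-branch likelihood profiles.

    For every partition the k constant patterns are appended as pseudo-
    characters so the ascertainment term is available from the same caches.
    For branch v with down partial D_v and up context U_v (the rest of the
    tree as a function of the parent state), the per-character likelihood as
    a function of that branch's length alone is
    ``(1/(kG)) sum_g sum_ij U_v[j] P_ji(t r_g) D_v[i]``.
    """

    def __init__(self, ev: MkEvaluator, tree: PhyloTree, shape: float):
        self.ev = ev
        model = ev.model if shape is None else replace(ev.model, shape=shape)
        _, self.rates = model.category_rates()
        self.asc = model.ascertainment == "variable_only"
        self.children, self.lengths, self.leaf_taxon, self.nodes = ev.struct(tree)
        n_taxa = ev.matrix.n_taxa
        self.parts = []
        for part in ev.partitions:
            k = part.k
            aug = np.concatenate(
                [part.tips, np.broadcast_to(np.eye(k)[None], (n_taxa, k, k))], axis=1
            )
            self.parts.append((k, len(part.chars), aug, part.chars))
        self.refresh()

    @staticmethod
    def _msg(x: np.ndarray, k: int, t: float, rates: np.ndarray) -> np.ndarray:
        e = np.exp(-k * rates * t / (k - 1))
        S = x.sum(axis=2)
        return ((1.0 - e)[None, :, None] / k) * S[:, :, None] + e[None, :, None] * x

    def refresh(self) -> None:
        """Recompute all down (D), message (M) and up (U) partials."""
        ch, lengths, lt, rates = self.children, self.lengths, self.leaf_taxon, self.rates
        N = len(ch)
        G = len(rates)
        self.cache = []
        for k, C_real, aug, chars in self.parts:
            C = aug.shape[1]
            D = [None] * N
            sD = np.zeros((N, C))
            M = [None] * N
            for v in range(N):
                if not ch[v]:
                    D[v] = np.broadcast_to(aug[lt[v]][:, None, :], (C, G, k)).copy()
                else:
                    acc = np.ones((C, G, k))
                    s = np.zeros(C)
                    for w in ch[v]:
                        acc = acc * M[w]
                        s += sD[w]
                    m = acc.max(axis=(1, 2))
                    if np.any(m <= 0):
                        raise ValueError("zero partial likelihood")
                    acc /= m[:, None, None]
                    s += np.log(m)
                    D[v] = acc
                    sD[v] = s
                if v != N - 1:
                    M[v] = self._msg(D[v], k, lengths[v], rates)
            U = [None] * N
            sU = np.zeros((N, C))
            A = [None] * N
            sA = np.zeros((N, C))
            A[N - 1] = np.ones((C, G, k))
            for v in range(N - 1, -1, -1):
                for w in ch[v]:
                    acc = A[v].copy()
                    s = sA[v].copy()
                    for w2 in ch[v]:
                        if w2 != w:
                            acc = acc * M[w2]
                            s += sD[w2]
                    m = acc.max(axis=(1, 2))
                    acc /= m[:, None, None]
                    s += np.log(m)
                    U[w] = acc
                    sU[w] = s
                    A[w] = self._msg(acc, k, lengths[w], rates)
                    sA[w] = s
            self.cache.append((k, C_real, D, sD, U, sU))

    def objective_at(self, v: int, t: float) -> float:
        """Total log-likelihood with branch v set to t (others fixed)."""
        G = len(self.rates)
        total = 0.0
        for k, C_real, D, sD, U, sU in self.cache:
            prof = self._msg(U[v], k, t, self.rates) * D[v]
            site = prof.sum(axis=(1, 2)) / (k * G)
            lnl = np.log(site) + sD[v] + sU[v]
            total += lnl[:C_real].sum()
            if self.asc:
                p_const = np.exp(lnl[C_real:]).sum()
                total -= C_real * math.log1p(-min(p_const, 1 - 1e-12))
        return total


def optimize_branch_lengths(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    model: MkModelSpec,
    optimize_shape: bool = True,
    max_sweeps: int = 20,
    tol: float = _LNL_TOL,
) -> LikelihoodResult:
    """Coordinate-wise branch-length (and shape) optimization on a fixed topology.

    Each branch is profiled against cached down/up partials and optimized by
    bounded Brent search in [1e-8, 20]; partials are refreshed after every
    branch (exact coordinate ascent) and sweeps repeat until the
    log-likelihood improves by less than ``tol``.
    """
    work = tree.copy()
    for nd in work.postorder():
        if nd is not work.root and (nd.length is None or nd.length <= 0):
            nd.length = 0.05
    ev = MkEvaluator(matrix, model)
    shape = model.shape
    cur = ev.loglik(work, shape)
    branch_nodes = [nd for nd in work.postorder() if nd is not work.root]
    for _ in range(max_sweeps):
        before = cur
        prof = _BranchProfiler(ev, work, shape)
        for v, nd in enumerate(branch_nodes):
            res = optimize.minimize_scalar(
                lambda t: -prof.objective_at(v, t),
                bounds=(BL_MIN, BL_MAX), method="bounded",
                options={"xatol": 1e-7},
            )
            if -res.fun >= cur - 1e-12:
                moved = abs(float(res.x) - (nd.length or 0.0))
                nd.length = float(res.x)
                prof.lengths[v] = float(res.x)
                cur = -res.fun
                if moved > 1e-9:
                    prof.refresh()
        if optimize_shape and model.rate_law != "equal":
            lo, hi = (1e-3, 1e3) if model.rate_law == "gamma" else (1e-4, 10.0)

            def g(s):
                return -ev.loglik(work, s)

            res = optimize.minimize_scalar(
                g, bounds=(lo, hi), method="bounded", options={"xatol": 1e-5}
            )
            shape = float(res.x)
            cur = -res.fun
        if cur - before < tol:
            break
    per_char = ev.per_char_loglik(work, shape)
    return LikelihoodResult(
        float(per_char.sum()), per_char, work, shape, replace(model, shape=shape)
    )


def _nni_variants(tree: PhyloTree) -> list[PhyloTree]:
    """Both nearest-neighbour interchanges around every internal edge."""
    out = []
    base = tree.copy()
    nodes = list(base.postorder())
    for idx, nd in enumerate(nodes):
        if nd.is_leaf or nd is base.root or len(nd.children) != 2:
            continue
        parent = nd.parent
        siblings = [c for c in parent.children if c is not nd]
        if not siblings:
            continue
        sib = siblings[0]
        for swap_child in (0, 1):
            cand = tree.copy()
            cnodes = list(cand.postorder())
            cnd = cnodes[idx]
            cpar = cnd.parent
            csib = [c for c in cpar.children if c is not cnd][0]
            moved = cnd.children[swap_child]
            # exchange moved <-> csib
            cnd.children[swap_child] = csib
            csib.parent = cnd
            cpar.children[cpar.children.index(csib)] = moved
            moved.parent = cpar
            out.append(cand)
    return out


def ml_search(
    matrix: CharacterMatrix,
    model: MkModelSpec,
    seed: int = 0,
    n_starts: int = 1,
    max_rounds: int = 20,
    parsimony_replicates: int = 3,
) -> tuple[PhyloTree, LikelihoodResult]:
    """Hill-climbing ML tree search: parsimony starting trees (plus random
    restarts), NNI moves screened at current branch lengths, winner re-optimized.
    Deterministic given ``seed``.
    """
    from . import parsimony as P

    rng = np.random.default_rng(seed)
    starts: list[PhyloTree] = []
    ts = P.heuristic_search(
        matrix,
        P.SearchConfig(
            n_replicates=parsimony_replicates, n_iterations=10,
            seed=int(rng.integers(2**31 - 1)), move_set="spr",
            plateau_limit=1,  # only one starting tree is needed
        ),
    )
    starts.append(ts.trees[0])
    for _ in range(n_starts - 1):
        starts.append(_random_topology(matrix.taxa, rng))

    best: LikelihoodResult | None = None
    quick = dict(max_sweeps=3, tol=1e-3)
    for start in starts:
        cur = optimize_branch_lengths(start, matrix, model, **quick)
        for _ in range(max_rounds):
            ev = MkEvaluator(matrix, cur.model)
            cands = _nni_variants(cur.tree)
            if not cands:
                break
            scores = [ev.loglik(c, cur.shape) for c in cands]
            order = int(np.argmax(scores))
            # re-optimize the screening winner to confirm the move
            trial = optimize_branch_lengths(cands[order], matrix, cur.model, **quick)
            if trial.log_likelihood > cur.log_likelihood + 1e-6:
                cur = trial
            else:
                break
        cur = optimize_branch_lengths(cur.tree, matrix, cur.model)
        if best is None or cur.log_likelihood > best.log_likelihood:
            best = cur
    return best.tree, best


def _random_topology(taxa: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    from . import parsimony as P

    order = rng.permutation(len(taxa))
    tree = P._initial_triple(int(order[0]), int(order[1]), int(order[2]), len(taxa))
    for leaf in order[3:]:
        edges = tree.edges()
        P._insert_leaf(tree, int(leaf), edges[rng.integers(len(edges))])
    return tree.to_phylo(list(taxa))


def bootstrap_support(
    matrix: CharacterMatrix,
    model: MkModelSpec,
    B: int = 100,
    seed: int = 0,
    best_tree: PhyloTree | None = None,
    search_kwargs: dict | None = None,
) -> dict[frozenset, float]:
    """Nonparametric bootstrap clade frequencies on the best tree's splits.

    Characters are resampled with replacement; each replicate is re-searched
    with reduced effort.  Support values are qualitative by design.
    """
    rng = np.random.default_rng(seed)
    kw = dict(n_starts=1, max_rounds=5, parsimony_replicates=1)
    kw.update(search_kwargs or {})
    if best_tree is None:
        best_tree, _ = ml_search(matrix, model, seed=int(rng.integers(2**31 - 1)), **kw)
    target = set(best_tree.splits())
    counts = {s: 0 for s in target}
    for _ in range(B):
        cols = rng.integers(0, matrix.n_characters, size=matrix.n_characters)
        bm = matrix.subset_characters([int(c) for c in cols])
        try:
            t, _ = ml_search(bm, model, seed=int(rng.integers(2**31 - 1)), **kw)
        except ValueError:
            continue  # e.g. a resampled partition lost all its states
        for s in t.splits():
            if s in counts:
                counts[s] += 1
    return {s: c / B for s, c in counts.items()}
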