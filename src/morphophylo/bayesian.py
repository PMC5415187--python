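"""Bayesian inference under Mk(V): MC3 sampling, diagnostics, model selection.

The posterior is over unrooted binary topologies (uniform prior), i.i.d.
exponential branch lengths, and the shape of the among-character rate law
(gamma alpha or lognormal sigma) under an exponential or uniform hyperprior.
Sampling is Metropolis-coupled MCMC: one cold chain plus heated chains with
heat 1/(1 + T*i), a proposal cycle of branch-length multipliers, NNI and SPR
topology moves and a shape multiplier, and one Metropolized state swap per
generation.

Marginal likelihoods are estimated by stepping-stone sampling along a ladder
of power posteriors with rungs at Beta(0.4, 1) quantiles, and compared with
Bayes factors on the 2*ln scale using the conventional 2/6/10 evidence
thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .likelihood import MkEvaluator, MkModelSpec, _random_topology
from .matrix import CharacterMatrix
from .trees import Node, PhyloTree, tree_from_clades


# -- configuration -------------------------------------------------------


@dataclass
class McmcConfig:
    """Run settings; defaults are the full-scale analysis profile
    (1e7 generations, 2 runs x 4 chains, heat 0.01, thin 1000, 25% burn-in).
    Desk-scale work passes smaller values explicitly.
    """

    n_generations: int = 10_000_000
    n_runs: int = 2
    n_chains: int = 4
    temperature: float = 0.01
    sample_every: int = 1000
    burnin_fraction: float = 0.25
    seed: int = 0
    shape_hyperprior: tuple = ("exponential", 1.0)  # or ("uniform", (0.0, 200.0))
    branch_length_prior_rate: float = 10.0
    fix_topology: bool = False
    link_branch_lengths: bool = False  # one shared branch-length parameter
    likelihood_power: float = 1.0

    def __post_init__(self):
        if not (0 <= self.burnin_fraction < 1):
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        kind = self.shape_hyperprior[0]
        if kind not in ("exponential", "uniform"):
            raise ValueError(f"unknown hyperprior {kind!r}")


@dataclass
class McmcState:
    tree: PhyloTree
    shape: float
    lnL: float
    ln_prior: float
    splits: frozenset = frozenset()


@dataclass
class PosteriorSample:
    states: list[McmcState]
    run_id: int
    config: McmcConfig
    swap_acceptance: float | None = None

    def post_burnin(self, burnin_fraction: float | None = None) -> list[McmcState]:
        f = self.config.burnin_fraction if burnin_fraction is None else burnin_fraction
        cut = int(math.floor(len(self.states) * f))
        return self.states[cut:]

    def param_trace(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.states])


@dataclass
class Diagnostics:
    asdsf: float
    psrf: dict[str, float]
    ess: dict[str, float]


@dataclass
class MarginalLikelihoodEstimate:
    model_label: str
    log_ml: float
    n_steps: int
    per_step_contributions: np.ndarray
    per_run_log_ml: np.ndarray | None = None
    std_error: float | None = None


@dataclass
class BayesFactor:
    m1: str
    m0: str
    log_bf: float

    @property
    def two_log_bf(self) -> float:
        return 2.0 * self.log_bf

    @property
    def verdict(self) -> str:
        b = abs(self.two_log_bf)
        if b > 10:
            return "very strong"
        if b > 6:
            return "strong"
        if b > 2:
            return "positive"
        return "none"


def bayes_factor(
    m1: MarginalLikelihoodEstimate, m0: MarginalLikelihoodEstimate
) -> BayesFactor:
    return BayesFactor(m1.model_label, m0.model_label, m1.log_ml - m0.log_ml)


# -- priors --------------------------------------------------------------


def _shape_log_prior(shape: float, hyper: tuple) -> float:
    kind = hyper[0]
    if kind == "exponential":
        rate = hyper[1]
        return math.log(rate) - rate * shape if shape > 0 else -math.inf
    lo, hi = hyper[1]
    return -math.log(hi - lo) if lo < shape < hi else -math.inf


def _draw_shape(hyper: tuple, rng: np.random.Generator) -> float:
    if hyper[0] == "exponential":
        return float(rng.exponential(1.0 / hyper[1]))
    lo, hi = hyper[1]
    return float(rng.uniform(lo, hi))


# -- chain state ---------------------------------------------------------


class _Chain:
    def __init__(
        self,
        tree: PhyloTree,
        shape: float,
        shared_bl: float | None,
        ev: MkEvaluator | None,
        config: McmcConfig,
        model: MkModelSpec,
    ):
        self.tree = tree
        self.shape = shape
        self.shared_bl = shared_bl  # None unless link_branch_lengths
        self.ev = ev
        self.config = config
        self.model = model
        self.lnL = self._loglik()
        self.ln_prior = self._log_prior()
        if not np.isfinite(self.lnL + self.ln_prior):
            raise ValueError("non-finite posterior at initialization")

    def _branches(self) -> list[Node]:
        return [nd for nd in self.tree.postorder() if nd.parent is not None]

    def _loglik(self) -> float:
        if self.ev is None:
            return 0.0
        if self.shared_bl is not None:
            for nd in self._branches():
                nd.length = self.shared_bl
        return self.ev.loglik(self.tree, self.shape)

    def _log_prior(self) -> float:
        lam = self.config.branch_length_prior_rate
        lp = _shape_log_prior(self.shape, self.config.shape_hyperprior) if (
            self.model.rate_law != "equal"
        ) else 0.0
        if self.shared_bl is not None:
            t = self.shared_bl
            return lp + (math.log(lam) - lam * t if t > 0 else -math.inf)
        for nd in self._branches():
            t = nd.length or 0.0
            lp += math.log(lam) - lam * t if t > 0 else -math.inf
        return lp

    def log_post(self, heat: float = 1.0, power: float = 1.0) -> float:
        return heat * (power * self.lnL + self.ln_prior)

    def snapshot(self) -> McmcState:
        return McmcState(
            self.tree.copy(), self.shape, self.lnL, self.ln_prior,
            frozenset(self.tree.splits().keys()) if self.tree.n_leaves >= 4 else frozenset(),
        )


def _apply_nni(tree: PhyloTree, rng: np.random.Generator) -> bool:
    cands = []
    for nd in tree.postorder():
        if (
            not nd.is_leaf
            and nd.parent is not None
            and len(nd.children) == 2
            and len(nd.parent.children) >= 2
        ):
            cands.append(nd)
    if not cands:
        return False
    nd = cands[rng.integers(len(cands))]
    par = nd.parent
    sibs = [c for c in par.children if c is not nd]
    sib = sibs[rng.integers(len(sibs))]
    child = nd.children[rng.integers(2)]
    # exchange child <-> sib, branch lengths travel with their subtrees
    i, j = nd.children.index(child), par.children.index(sib)
    nd.children[i], par.children[j] = sib, child
    sib.parent, child.parent = nd, par
    return True


def _apply_spr(tree: PhyloTree, rng: np.random.Generator) -> float | None:
    """Prune-and-regraft keeping the pruned edge length; the target edge is
    split uniformly.  Returns the log-Hastings ratio, or None if no valid move.
    """
    nodes = [
        nd
        for nd in tree.postorder()
        if nd.parent is not None and nd.parent.parent is not None
    ]
    if not nodes:
        return None
    v = nodes[rng.integers(len(nodes))]
    p = v.parent
    q = p.parent
    s = [c for c in p.children if c is not v][0]
    # detach v, suppress p
    merged = (p.length or 0.0) + (s.length or 0.0)
    q.children[q.children.index(p)] = s
    s.parent = q
    s.length = merged
    # candidate targets: any node with a parent, outside v's subtree, not s
    sub = set()
    stack = [v]
    while stack:
        x = stack.pop()
        sub.add(id(x))
        stack.extend(x.children)
    targets = [
        nd
        for nd in tree.postorder()
        if nd.parent is not None and id(nd) not in sub
    ]
    w = targets[rng.integers(len(targets))]
    tw = w.length or 0.0
    u = rng.uniform()
    wp = w.parent
    newp = Node(length=u * tw)
    wp.children[wp.children.index(w)] = newp
    newp.parent = wp
    newp.add_child(w)
    w.length = (1 - u) * tw
    newp.add_child(v)
    if tw <= 0 or merged <= 0:
        return 0.0
    return math.log(tw) - math.log(merged)


# -- the sampler ---------------------------------------------------------


def _init_chain(
    matrix: CharacterMatrix,
    model: MkModelSpec,
    config: McmcConfig,
    rng: np.random.Generator,
    ev: MkEvaluator | None,
    start_tree: PhyloTree | None = None,
) -> _Chain:
    if start_tree is not None:
        tree = start_tree.copy()
    else:
        tree = _random_topology(matrix.taxa, rng)
    mean_bl = 1.0 / config.branch_length_prior_rate
    for nd in tree.postorder():
        if nd.parent is not None and nd.length is None:
            nd.length = float(rng.exponential(mean_bl))
    shape = (
        _draw_shape(config.shape_hyperprior, rng)
        if model.rate_law != "equal"
        else model.shape
    )
    if model.rate_law == "gamma":
        shape = max(shape, 1e-3)
    shared = float(rng.exponential(mean_bl)) if config.link_branch_lengths else None
    return _Chain(tree, shape, shared, ev, config, model)


def _step(chain: _Chain, rng: np.random.Generator, heat: float, power: float) -> bool:
    cfg = chain.config
    moves = ["blen", "blen", "blen"]
    if not cfg.fix_topology and chain.tree.n_leaves >= 4:
        moves += ["nni", "nni", "spr"]
    if chain.model.rate_law != "equal":
        moves.append("shape")
    if cfg.link_branch_lengths:
        moves = [m for m in moves if m not in ("blen",)] + ["shared", "shared"]
    move = moves[rng.integers(len(moves))]

    old = (chain.tree, chain.shape, chain.shared_bl, chain.lnL, chain.ln_prior)
    log_hastings = 0.0
    if move == "blen":
        chain.tree = chain.tree.copy()
        branches = chain._branches()
        nd = branches[rng.integers(len(branches))]
        mult = math.exp(1.0 * (rng.uniform() - 0.5))
        nd.length = (nd.length or 1e-6) * mult
        log_hastings = math.log(mult)
    elif move == "shared":
        mult = math.exp(1.0 * (rng.uniform() - 0.5))
        chain.shared_bl = chain.shared_bl * mult
        log_hastings = math.log(mult)
    elif move == "shape":
        mult = math.exp(1.2 * (rng.uniform() - 0.5))
        chain.shape = chain.shape * mult
        log_hastings = math.log(mult)
    elif move == "nni":
        chain.tree = chain.tree.copy()
        if not _apply_nni(chain.tree, rng):
            chain.tree = old[0]
            return False
    elif move == "spr":
        chain.tree = chain.tree.copy()
        h = _apply_spr(chain.tree, rng)
        if h is None:
            chain.tree = old[0]
            return False
        log_hastings = h
    old_post = heat * (power * old[3] + old[4])
    try:
        chain.lnL = chain._loglik()
        chain.ln_prior = chain._log_prior()
    except ValueError:
        chain.tree, chain.shape, chain.shared_bl, chain.lnL, chain.ln_prior = old
        return False
    new_post = chain.log_post(heat, power)
    if math.log(rng.uniform() + 1e-300) < new_post - old_post + log_hastings:
        return True
    chain.tree, chain.shape, chain.shared_bl, chain.lnL, chain.ln_prior = old
    return False


def run_mcmc(
    matrix: CharacterMatrix,
    model: MkModelSpec,
    config: McmcConfig,
    start_tree: PhyloTree | None = None,
) -> list[PosteriorSample]:
    """Metropolis-coupled MCMC; returns one PosteriorSample per independent run.

    Deterministic given ``config.seed``; run- and chain-level RNG streams are
    derived from it.  The cold chain is recorded every ``sample_every``
    generations including the initial state.
    """
    ev = _make_evaluator(matrix, model)
    out = []
    for run in range(config.n_runs):
        rng = np.random.default_rng([config.seed % (2**31), 7919 + run])
        chains = [
            _init_chain(matrix, model, config, rng, ev, start_tree)
            for _ in range(config.n_chains)
        ]
        heats = [1.0 / (1.0 + config.temperature * i) for i in range(config.n_chains)]
        states = [chains[0].snapshot()]
        swaps_tried = swaps_ok = 0
        for gen in range(1, config.n_generations + 1):
            for i, ch in enumerate(chains):
                _step(ch, rng, heats[i], config.likelihood_power)
            if config.n_chains > 1:
                i = int(rng.integers(config.n_chains - 1))
                j = i + 1
                a, b = chains[i], chains[j]
                delta = (heats[i] - heats[j]) * (
                    b.log_post(1.0, config.likelihood_power)
                    - a.log_post(1.0, config.likelihood_power)
                )
                swaps_tried += 1
                if math.log(rng.uniform() + 1e-300) < delta:
                    chains[i], chains[j] = b, a
                    swaps_ok += 1
            if gen % config.sample_every == 0:
                states.append(chains[0].snapshot())
        out.append(
            PosteriorSample(
                states, run, config,
                swap_acceptance=(swaps_ok / swaps_tried) if swaps_tried else None,
            )
        )
    return out


def _make_evaluator(matrix: CharacterMatrix, model: MkModelSpec) -> MkEvaluator | None:
    ev = MkEvaluator(matrix, model)
    return ev if ev.partitions else None


# -- diagnostics ---------------------------------------------------------


def effective_sample_size(x: Sequence[float]) -> float:
    """Autocorrelation-time ESS with Geyer's initial-positive-sequence cutoff."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 4 or np.ptp(x) == 0:
        return float(n)
    x = x - x.mean()
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    rho = acov / acov[0]
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(n, n / tau))


def split_frequencies(states: Sequence[McmcState]) -> dict[frozenset, float]:
    counts: dict[frozenset, int] = {}
    for s in states:
        for sp in s.splits:
            counts[sp] = counts.get(sp, 0) + 1
    return {sp: c / len(states) for sp, c in counts.items()}


def _psrf(traces: list[np.ndarray]) -> float:
    m = len(traces)
    n = min(len(t) for t in traces)
    if m < 2 or n < 2:
        return float("nan")
    arr = np.stack([t[:n] for t in traces])
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B_over_n
    return float(math.sqrt(var_hat / W))


def compute_diagnostics(
    samples: Sequence[PosteriorSample], burnin_fraction: float | None = None
) -> Diagnostics:
    """ASDSF over splits with pooled frequency >= 0.10, PSRF and ESS for the
    log-likelihood and shape traces."""
    runs = [s.post_burnin(burnin_fraction) for s in samples]
    per_run = [split_frequencies(r) for r in runs]
    pooled: dict[frozenset, float] = {}
    total = sum(len(r) for r in runs)
    for freqs, r in zip(per_run, runs):
        for sp, f in freqs.items():
            pooled[sp] = pooled.get(sp, 0.0) + f * len(r) / total
    keep = [sp for sp, f in pooled.items() if f >= 0.10]
    if keep and len(runs) > 1:
        devs = [
            np.std([fr.get(sp, 0.0) for fr in per_run], ddof=1) for sp in keep
        ]
        asdsf = float(np.mean(devs))
    else:
        asdsf = 0.0
    psrf, ess = {}, {}
    for name in ("lnL", "shape"):
        traces = [np.array([getattr(s, name) for s in r]) for r in runs]
        psrf[name] = _psrf(traces)
        ess[name] = float(sum(effective_sample_size(t) for t in traces))
    return Diagnostics(asdsf=asdsf, psrf=psrf, ess=ess)


# -- posterior summaries -------------------------------------------------


def _pooled_states(
    samples: Sequence[PosteriorSample], burnin_fraction: float | None
) -> list[McmcState]:
    pooled: list[McmcState] = []
    for s in samples:
        pooled.extend(s.post_burnin(burnin_fraction))
    if not pooled:
        raise ValueError("no post-burn-in samples")
    return pooled


def majority_rule_tree(
    samples: Sequence[PosteriorSample],
    burnin_fraction: float | None = None,
    threshold: float = 0.5,
) -> PhyloTree:
    """Majority-rule consensus of pooled post-burn-in trees, annotated with
    posterior clade probabilities and mean branch lengths."""
    pooled = _pooled_states(samples, burnin_fraction)
    freqs = split_frequencies(pooled)
    keep = {sp: f for sp, f in freqs.items() if f > threshold}
    labels = pooled[0].tree.leaf_labels
    cons = tree_from_clades(labels, keep)
    # mean branch lengths per clade / per leaf
    sums: dict[frozenset, float] = {}
    counts: dict[frozenset, int] = {}
    for st in pooled:
        splits = st.tree.splits()
        for sp, nd in splits.items():
            if sp in keep and nd.length is not None:
                sums[sp] = sums.get(sp, 0.0) + nd.length
                counts[sp] = counts.get(sp, 0) + 1
        for leaf in st.tree.leaves():
            key = frozenset([leaf.label])
            if leaf.length is not None:
                sums[key] = sums.get(key, 0.0) + leaf.length
                counts[key] = counts.get(key, 0) + 1
    cons_splits = cons.splits()
    for sp, nd in cons_splits.items():
        if sp in counts:
            nd.length = sums[sp] / counts[sp]
    for leaf in cons.leaves():
        key = frozenset([leaf.label])
        if key in counts:
            leaf.length = sums[key] / counts[key]
    return cons


def mcc_tree(
    samples: Sequence[PosteriorSample], burnin_fraction: float | None = None
) -> PhyloTree:
    """The sampled topology maximizing the product of its clades' posterior
    probabilities; ties break to the more frequently sampled topology, then
    to the earlier-sampled one."""
    pooled = _pooled_states(samples, burnin_fraction)
    freqs = split_frequencies(pooled)
    seen: dict[frozenset, tuple[int, int, McmcState]] = {}
    for idx, st in enumerate(pooled):
        key = st.splits
        if key in seen:
            cnt, first, rep = seen[key]
            seen[key] = (cnt + 1, first, rep)
        else:
            seen[key] = (1, idx, st)
    best_key, best = None, None
    for key, (cnt, first, rep) in seen.items():
        score = sum(math.log(freqs[sp]) for sp in key)
        item = (score, cnt, -first)
        if best is None or item > best:
            best, best_key = item, key
    rep = seen[best_key][2]
    tree = rep.tree.copy()
    for sp, nd in tree.splits().items():
        nd.annotations["support"] = freqs[sp]
    tree.root.annotations["clade_credibility"] = math.exp(best[0]) if best_key else 1.0
    return tree


# -- stepping-stone marginal likelihood ----------------------------------


def stepping_stone(
    matrix: CharacterMatrix,
    model: MkModelSpec,
    config: McmcConfig,
    n_steps: int = 50,
    per_step_generations: int = 2000,
    model_label: str | None = None,
) -> MarginalLikelihoodEstimate:
    """Stepping-stone estimate of the marginal log-likelihood.

    The power ladder puts rungs at the quantiles of Beta(0.4, 1); the chain
    anneals from the posterior toward the prior, spending
    ``per_step_generations`` at each rung (first 25% discarded) and the
    contribution of each interval is the log mean importance weight from the
    rung below it.  ``config.n_runs`` independent ladders give the mean and
    its standard error, as in replicate-run reporting.
    """
    ev = _make_evaluator(matrix, model)
    K = n_steps
    betas = (np.arange(K + 1) / K) ** (1.0 / 0.4)
    per_run = []
    contribs_first = None
    for run in range(max(1, config.n_runs)):
        rng = np.random.default_rng([config.seed % (2**31), 104729 + run])
        chain = _init_chain(matrix, model, config, rng, ev)
        # settle at the posterior before stepping down
        for _ in range(per_step_generations):
            _step(chain, rng, 1.0, 1.0)
        contribs = np.zeros(K)
        for j in range(K - 1, -1, -1):
            beta = betas[j]
            burn = per_step_generations // 4
            lnls = []
            for g in range(per_step_generations):
                _step(chain, rng, 1.0, beta)
                if g >= burn:
                    lnls.append(chain.lnL)
            lnls = np.asarray(lnls)
            w = (betas[j + 1] - beta) * lnls
            if np.ptp(w) > 200:
                import warnings

                warnings.warn(f"degenerate stepping-stone weights at beta={beta:.4g}")
            contribs[j] = logsumexp(w) - math.log(len(w))
        per_run.append(float(contribs.sum()))
        if contribs_first is None:
            contribs_first = contribs
    per_run = np.asarray(per_run)
    se = float(per_run.std(ddof=1) / math.sqrt(len(per_run))) if len(per_run) > 1 else None
    return MarginalLikelihoodEstimate(
        model_label or f"{config.shape_hyperprior[0]}-{model.rate_law}",
        float(per_run.mean()),
        K,
        contribs_first,
        per_run_log_ml=per_run,
        std_error=se,
    )
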