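"""Tree-comparison tests: Templeton (Wilcoxon signed-ranks) and SH/RELL.

The Templeton test compares two topologies by the per-character differences
in parsimony steps, dropping zero differences and using mid-ranks for ties;
the null distribution is enumerated exactly when twelve or fewer characters
differ, otherwise the tie-corrected, continuity-corrected normal
approximation is used (via scipy).

The SH test compares a candidate set of topologies on per-character
log-likelihoods (branch lengths optimized per candidate), using RELL
bootstrap resampling with per-replicate centering; the maximum-likelihood
tree has p = 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .likelihood import MkModelSpec, optimize_branch_lengths
from .matrix import CharacterMatrix
from .parsimony import ParsimonyEngine
from .trees import PhyloTree


@dataclass
class TempletonResult:
    p: float
    statistic: float  # signed-rank sum of positive differences (W+)
    n_nonzero: int
    exact: bool


@dataclass
class TopologyTestResult:
    tree_label: str
    length: int
    templeton_p: float | None
    neg_lnL: float | None
    sh_p: float | None


def templeton_test(
    tree_a: PhyloTree,
    tree_b: PhyloTree,
    matrix: CharacterMatrix,
    exact_limit: int = 12,
) -> TempletonResult:
    """Two-tailed Wilcoxon signed-ranks test on per-character step differences.

    Symmetric in its tree arguments; identical trees (no nonzero differences)
    give p = 1.
    """
    if set(tree_a.leaf_labels) != set(tree_b.leaf_labels):
        raise ValueError("trees must share one leaf set")
    eng = ParsimonyEngine(matrix)
    d = eng.per_char_steps(tree_b).astype(float) - eng.per_char_steps(tree_a)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TempletonResult(1.0, 0.0, 0, True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        # enumerate all sign assignments under the null
        mu = ranks.sum() / 2.0
        obs = abs(w_plus - mu)
        hits = 0
        for bits in range(1 << n):
            w = sum(ranks[i] for i in range(n) if bits >> i & 1)
            if abs(w - mu) >= obs - 1e-12:
                hits += 1
        return TempletonResult(hits / (1 << n), w_plus, n, True)
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=True, alternative="two-sided",
        method="approx",
    )
    return TempletonResult(float(res.pvalue), w_plus, n, False)


def templeton_range(
    focal: PhyloTree,
    others: Sequence[PhyloTree],
    matrix: CharacterMatrix,
) -> tuple[float, float]:
    """Range of Templeton p-values of a focal tree against a pool of trees."""
    ps = [templeton_test(focal, t, matrix).p for t in others]
    return min(ps), max(ps)


def sh_test(
    candidate_trees: Sequence[PhyloTree],
    matrix: CharacterMatrix,
    model: MkModelSpec,
    B: int = 1000,
    seed: int = 0,
    optimize: bool = True,
    per_char_lnl: np.ndarray | None = None,
) -> list[tuple[PhyloTree, float, float]]:
    """Shimodaira-Hasegawa test over a candidate topology set.

    Branch lengths are re-optimized per candidate unless precomputed
    per-character log-likelihoods are supplied (rows = trees).  Returns
    ``(tree, sh_p, lnL)`` per candidate; the best tree has p = 1.
    """
    T = len(candidate_trees)
    if per_char_lnl is None:
        rows = []
        for t in candidate_trees:
            if optimize:
                res = optimize_branch_lengths(t, matrix, model)
            else:
                from .likelihood import tree_log_likelihood

                res = tree_log_likelihood(t, matrix, model)
            rows.append(res.per_char_lnL)
        per_char_lnl = np.stack(rows)
    C = per_char_lnl.shape[1]
    totals = per_char_lnl.sum(axis=1)
    delta_obs = totals.max() - totals  # lnL deficit per tree
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, C, size=(B, C))
    # RELL: resampled totals, (B, T)
    R = per_char_lnl[:, idx].sum(axis=2).T
    Rc = R - R.mean(axis=0, keepdims=True)  # center per tree
    S = Rc.max(axis=1, keepdims=True)
    exceed = (S - Rc) >= delta_obs[None, :] - 1e-12
    p = exceed.mean(axis=0)
    return [
        (t, float(p[i]), float(totals[i])) for i, t in enumerate(candidate_trees)
    ]


def topology_test_table(
    labelled_trees: Sequence[tuple[str, PhyloTree]],
    matrix: CharacterMatrix,
    model: MkModelSpec,
    reference: PhyloTree | None = None,
    B: int = 1000,
    seed: int = 0,
) -> list[TopologyTestResult]:
    """Summary table: parsimony length, Templeton p against the reference
    (best) tree, optimized -lnL and SH p for each labelled candidate."""
    eng = ParsimonyEngine(matrix)
    trees = [t for _, t in labelled_trees]
    if reference is None:
        lengths = [int(eng.per_char_steps(t).sum()) for t in trees]
        reference = trees[int(np.argmin(lengths))]
    sh = sh_test(trees, matrix, model, B=B, seed=seed)
    out = []
    for (label, tree), (_, p_sh, lnl) in zip(labelled_trees, sh):
        out.append(
            TopologyTestResult(
                tree_label=label,
                length=int(eng.per_char_steps(tree).sum()),
                templeton_p=templeton_test(reference, tree, matrix).p,
                neg_lnL=-lnl,
                sh_p=p_sh,
            )
        )
    return out
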