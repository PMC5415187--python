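# Methods

This note describes the models and algorithms implemented in `morphophylo`,
the choices made where the design was genuinely open, and what the synthetic
data used by the tests does and does not establish.

## Data model

A `CharacterMatrix` holds taxa by discrete characters; every cell is a
non-empty set of state indices (singleton = unambiguous score, larger set =
polymorphism or partial uncertainty, full set = unknown). `?` (missing) and
`-` (inapplicable) both decode to the full state set and are computationally
identical everywhere; the distinction is preserved only for round-tripping,
which is how both the parsimony and the model-based programs this package
mirrors behave. A character's state count `k` is the highest attested state
index plus one (a character scored only 0 and 2 is three-state), floored at
two so that binary characters with missing entries stay binary; a simulation
or NEXUS caller can widen `k` explicitly. Character indices are 0-based in
code and 1-based in every user-facing report.

NEXUS and Newick parsing go through dendropy; writing is a small emitter
whose output dendropy re-reads (polymorphism dialect configurable between
`(..)` and `{..}`; ordered characters via an ASSUMPTIONS `TYPESET`).

The contingent-to-multistate recoding (`merge_contingent_characters`)
folds dependent binary characters into their host transformation series via
an explicit joint-state table. Joint states not in the table fall back to the
host state unchanged (the usual case: the dependent character is
inapplicable); disabling the fallback turns unmatched joint states into
errors. The operation is generic: any recoding map can be applied. The maps
exercised in the tests and examples are synthetic; a published merge table
(these live in journal supplements) is supplied by the user as a
`RecodingMap`.

## Parsimony

Character fit is a vectorized Sankoff dynamic program over a step matrix —
unit steps for unordered characters, `|i-j|` for ordered ones — which reduces
exactly to Fitch counting (unordered) and the Farris interval algorithm
(ordered) on binary trees and stays exact on hard polytomies and ambiguous
cells. Per-character minimum steps `m` use a minimum hitting set over cell
state-sets (exact for k ≤ 6); maximum steps `g` are the star-tree cost with
ambiguous cells assigned optimally against the best median. The ensemble
indices are CI = Σm/Σs and RI = (Σg−Σs)/(Σg−Σm), summed over variable
characters including autapomorphies (the TNT reporting convention), with an
informative-only option.

Implied weighting minimizes the distortion F = Σ h/(h+K) with homoplasy
h = s − m and concavity K (default 3.0); the concave complement C−F is also
reported so either reporting convention can be checked.

Searches are random-addition Wagner trees followed by TBR hill climbing on
an unrooted adjacency representation, with an SPR-restricted mode used
automatically above 24 taxa (the full TBR neighbourhood is cubic in taxa).
Ties during Wagner addition break uniformly at random under the run seed.
Equally optimal trees are pooled across replicates, a bounded plateau sweep
collects further equal-score neighbours, and topologies are deduplicated on
their unrooted splits (hold default 10,000). Tied-tree counts depend on the
collapsing convention of the program that printed them, so counts are
reported but treated as non-binding.

## Mk likelihood

The substitution model is the k-state Mk chain (equal rates, stationary
frequencies 1/k) scaled to one expected change per unit branch length, so
transition probabilities have a closed form and pruning messages reduce to
`(1−e)/k·Σx + e·x`. Characters are partitioned by state count; each
partition gets its own Mk dimension and its own ascertainment term, sharing
one rate law — mirroring how standard-data models treat mixed state counts.

Among-character rate variation uses G equal-probability discrete categories
of a mean-one gamma (shape α) or lognormal (σ, location −σ²/2) distribution,
category rates being the conditional means of each quantile slice,
renormalized to mean one (within 1e-10). The lognormal law is available to
maximum likelihood as well, using the same discretization as the Bayesian
module. Defaults: 8 categories for ML, 4 for MCMC.

The variable-only (Mk(V)) correction divides each character's likelihood by
one minus the sum of the k constant-pattern likelihoods of its partition,
computed with all taxa scored. A fully scored invariant character is
rejected under this model; characters constant only through missing data are
legal and scored normally, and an entirely missing character contributes
exactly zero.

Branch-length optimization profiles one branch at a time against cached
down/up partials (the constant patterns ride along as pseudo-characters so
the ascertainment term tracks the branch being moved), refreshing the caches
after every accepted move — exact coordinate ascent — with bounded Brent
steps in [1e-8, 20] and sweeps until the log-likelihood gains less than 1e-6
(coarser settings are used while screening tree rearrangements). Numerical
stability comes from per-node, per-character rescaling; all logarithms are
natural.

Tree search is NNI hill climbing from a parsimony starting tree (plus
optional random restarts): candidates are screened at current branch
lengths, the winner re-optimized, and the final tree polished at full
tolerance. Branch support is a standard nonparametric character bootstrap
with reduced search effort per replicate; support values are qualitative by
design and nothing downstream depends on them numerically.

## Bayesian inference

The posterior is over unrooted binary topologies (uniform), i.i.d.
exponential(10) branch lengths, and the rate-law shape under an
exponential(1) or uniform(0, 200) hyperprior — MrBayes-style defaults, all
configurable, since the analysis this mirrors states only the prior
families. Sampling is Metropolis-coupled MCMC: heat of chain i is
1/(1 + T·i) (T default 0.01), a proposal cycle of branch-length multipliers,
NNI, SPR (target edge split uniformly; Hastings ratio t_target/t_merged) and
a shape multiplier, and one Metropolized swap attempt per generation. The
cold chain is recorded every `sample_every` generations including the
initial state, so two runs of N generations thinned by s pool 2(N/s + 1)
trees. Per-run and per-chain RNG streams derive from one master seed.

A run on an all-missing matrix has constant likelihood and therefore samples
the prior exactly; the test suite uses this for distributional validation of
every prior marginal (shape, branch lengths, uniform topologies). Note the
conditioning term is parameter-dependent, so this check is only "data-free"
because empty characters drop out of the partition set entirely.

Diagnostics: ASDSF over splits with pooled frequency ≥ 0.10 (sample standard
deviation across runs), Gelman-Rubin PSRF for the log-likelihood and shape
traces, and autocorrelation-time ESS with Geyer's initial-positive-sequence
truncation (validated against the AR(1) closed form).

Posterior summaries: majority-rule consensus with posterior clade
probabilities and mean branch lengths, and the maximum clade credibility
topology (argmax over sampled topologies of the product of clade posterior
probabilities; ties break to the more frequently sampled, then the
earlier-sampled topology). MCC clades need not all reach majority frequency.

Marginal likelihoods use stepping-stone sampling along a Beta(0.4, 1)
quantile ladder (default 50 rungs), annealing from the posterior toward the
prior, 25% burn-in per rung, each interval contributing the log mean
importance weight from the rung below. Replicate ladders give the mean and
standard error. Bayes factors are reported on the 2·ln scale with the
conventional 2/6/10 thresholds (positive / strong / very strong).

## Topology tests

The Templeton test compares two trees on per-character parsimony step
differences: zeros dropped, mid-ranks for ties, exact enumeration of the
2^n sign assignments when n ≤ 12 nonzero differences, otherwise the
tie-corrected continuity-corrected normal approximation (scipy). Two-tailed
and symmetric in its arguments; identical trees give p = 1. Against a pool
of equally parsimonious trees the p-value range is reported.

The SH test uses per-character log-likelihoods with branch lengths
re-optimized per candidate topology, RELL bootstrap resampling, per-tree
centering, and the maximum over the candidate set; the best tree has p = 1
by construction. Consensus trees with polytomies are scored as hard
multifurcations under both parsimony and likelihood.

## Ancestral reconstruction

Parsimony reconstruction returns full MPR state sets per node (Sankoff
down-pass plus an up-pass scoring the rest of the tree for each candidate
state), exact on polytomies and ordered characters. Likelihood
reconstruction follows the one-parameter "Mk1" convention of
character-mapping tools: a single rate fitted by maximizing that character's
likelihood on the given tree (branch lengths fixed), flat 1/k root
frequencies, and marginal state probabilities by re-rooted pruning at every
node. A character with fewer than two attested states is flagged degenerate,
and a named clade that is not monophyletic on the tree is reported as such
with no numbers — the two conditions are distinguished in the report.

## Synthetic data

The generator evolves each character independently under Mk on a known tree
(uniform random topology, exponential branch lengths), with state counts
mixed over k = 2–4 (default weights 0.7/0.2/0.1), rates drawn from the
configured mean-one law, optional rejection sampling until the character is
variable, a low polymorphism rate (default 0.5%) to exercise ambiguity
handling, and missing data applied as per-taxon blocks of contiguous
characters — imitating fossil incompleteness, where whole anatomical regions
are unknown — rather than i.i.d. cells.

The flagship fixture is 44 taxa by 125 characters with roughly 30% of cells
missing, concentrated in a third of the taxa, gamma rates (α = 1), mean
branch length 0.12, conditioned on variability; over half its characters are
parsimony-informative. These values were fixed once as a realistic
fossil-matrix regime and are not tuned.

What passing tests on such data show: the algorithms correctly implement
their models (verified against exhaustive enumeration, quadrature and
closed-form oracles) and recover generating parameters and topologies under
the models' own assumptions. What they do not show: robustness to correlated
characters, heterotachy, nonstationary coding practices, or
non-block-structured missingness — none of which the generator emulates.

## Problem sizes and numerical choices

The default test and acceptance runs use desk-scale sizes chosen as the
package's own testing regime: parsimony oracle checks at 6–7 taxa
(exhaustive enumeration over 105/945 topologies, ≥ 50 random matrices),
likelihood oracles at 3–4 taxa, MCMC validation at 10^4–10^5 generations,
stepping stone at 8–25 rungs, gamma-shape recovery at 2000 characters
(quadrature at 12 categories, since coarse discretization itself biases the
shape estimate at α ≈ 0.3), and ML topology recovery at 20 taxa and 500
characters under a strong-signal tree (branch lengths clamped to
[0.05, 0.6]): weak internal branches of a few thousandths of a change are
irrecoverable at this length in principle, which is a property of the data,
not the search. Full-scale settings (10^7 generations, 50 rungs, 100×100
search replicates) are available through the `full` pipeline profile.

Known limitations: the SPR-restricted search mode trades neighbourhood
completeness for speed above 24 taxa; the MCC tree reports the
branch lengths of its first sampled representative; stepping-stone standard
errors come from replicate ladders, not within-run autocorrelation; and
bootstrap supports use reduced search effort per replicate.
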