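"""Ancestral-state reconstruction: parsimony MPR sets and Mk1 marginals.

Reconstructs a binary character (think: a skeletal adaptation present or
absent) on a known tree with both methods and prints the root and a named
clade's ancestor.
"""

import morphophylo as mp

matrix, truth = mp.simulate_matrix(
    mp.SimulationSpec(n_taxa=10, n_characters=30, state_weights={2: 1.0},
                      seed=23, missing_fraction_beta=None)
)
tree = truth.tree
char = 0

mpr = mp.parsimony_ancestral_states(tree, matrix, char)
# an MPR set lists every state that appears in at least one
# most-parsimonious labelling; more than one state = ambiguous node
root_states = "/".join(str(s) for s in sorted(mpr.states_of(tree.root)))
print(f"parsimony MPR at the root: state(s) {root_states}")

mk1 = mp.likelihood_ancestral_states(tree, matrix, char)
p = mk1.states_of(tree.root)
print(f"Mk1 marginals at the root: P(0) {p[0]:.3f}  P(1) {p[1]:.3f}  "
      f"(fitted rate {mk1.rate_estimate:.3f})")

# pick a cherry (two-leaf clade) that actually exists on the tree, plus a
# deliberately non-monophyletic pair to show the flagged row
cherry = next(
    nd for nd in tree.postorder()
    if not nd.is_leaf and all(c.is_leaf for c in nd.children)
    and len(nd.children) == 2
)
pair = [c.label for c in cherry.children]
scattered = [pair[0], next(l for l in tree.leaf_labels if l not in pair)]
report = mp.clade_ancestor_report(
    mk1, {"cherry": pair, "scattered": scattered}
)
print(report.to_string(index=False))
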