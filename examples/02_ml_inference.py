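"""Maximum-likelihood inference under Mk + gamma rates + ascertainment bias.

Simulates a matrix of variable-only characters, runs the NNI/branch-length
hill-climbing search, and prints the optimum, the fitted shape and the
distance to the generating tree.
"""

import morphophylo as mp

matrix, truth = mp.simulate_matrix(
    mp.SimulationSpec(n_taxa=10, n_characters=400, rate_law="gamma", shape=0.8,
                      seed=7, missing_fraction_beta=None)
)
model = mp.MkModelSpec(rate_law="gamma", n_categories=8,
                       ascertainment="variable_only")
tree, result = mp.ml_search(matrix, model, seed=3)

# -lnL: the optimized negative log-likelihood (smaller = better fit);
# shape: the fitted gamma alpha -- values < 1 mean strong rate variation
print(f"-lnL {-result.log_likelihood:.3f}  fitted alpha {result.shape:.3f} "
      f"(generating value 0.8; shape estimates are noisy at 10 taxa)")
print(f"RF distance to the generating tree: {tree.rf_distance(truth.tree)} "
      f"(0 = identical)")

# per-character log-likelihoods feed the SH topology test downstream
worst = result.per_char_lnL.argmin()
print(f"least-well-explained character: {worst + 1} "
      f"(lnL {result.per_char_lnL[worst]:.2f})")
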