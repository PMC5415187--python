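import numpy as np
import pytest

from morphophylo.matrix import CharacterMatrix
from morphophylo.trees import PhyloTree


@pytest.fixture
def quartet_tree():
    return PhyloTree.from_newick("((A,B),(C,D));")


@pytest.fixture
def quartet_matrix():
    return CharacterMatrix.from_rows(
        ["A", "B", "C", "D"],
        [[0, 0, 1], [0, 1, "?"], [1, {0, 1}, 0], [1, 1, 2]],
    )


def random_matrix(rng, n_taxa, n_chars, k_max=3, missing_p=0.1, n_states=None):
    """Small random matrix with occasional ambiguity, for oracle tests."""
    taxa = [chr(ord("A") + i) for i in range(n_taxa)]
    rows = []
    for _ in range(n_taxa):
        row = []
        for c in range(n_chars):
            k = 2 if k_max == 2 else int(rng.integers(2, k_max + 1))
            u = rng.uniform()
            if u < missing_p:
                row.append("?")
            elif u < missing_p + 0.05:
                row.append(frozenset(rng.choice(k, size=2, replace=False).tolist()))
            else:
                row.append(int(rng.integers(k)))
        rows.append(row)
    return CharacterMatrix.from_rows(taxa, rows, n_states=n_states)
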