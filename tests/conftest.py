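"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from quartetstar import QuartetTree, transition_prob
from quartetstar.likelihood import PAIRINGS


def brute_force_column_prob(column, tree: QuartetTree, r: float = 1.0) -> float:
    """Probability of one 4-nucleotide column by explicit state enumeration.

    Independent oracle for the pruning algorithm: sums over all assignments
    of internal-node states (4 for a star, 16 for a resolved tree) using the
    scalar closed-form transition probability.
    """
    nucs = "ACGT"
    if tree.is_star:
        total = 0.0
        for x in nucs:
            p = 0.25
            for k in range(4):
                p *= transition_prob(x, column[k], r * tree.b[k])
            total += p
        return total
    (i, j), (k, l) = PAIRINGS[tree.topology]
    total = 0.0
    for x in nucs:
        for y in nucs:
            p = 0.25
            p *= transition_prob(x, column[i], r * tree.b[i])
            p *= transition_prob(x, column[j], r * tree.b[j])
            p *= transition_prob(x, y, r * tree.b5)
            p *= transition_prob(y, column[k], r * tree.b[k])
            p *= transition_prob(y, column[l], r * tree.b[l])
            total += p
    return total


def all_columns():
    """All 256 raw site patterns as 4-tuples of nucleotides."""
    return list(itertools.product("ACGT", repeat=4))


@pytest.fixture(scope="session")
def random_trees():
    """A deterministic batch of star and resolved trees with varied branches."""
    rng = np.random.default_rng(20240917)
    trees = []
    for _ in range(5):
        b = tuple(rng.uniform(0.05, 3.0, size=4))
        trees.append(QuartetTree("star", b))
        for topo in PAIRINGS:
            trees.append(QuartetTree(topo, b, rng.uniform(0.0, 2.0)))
    return trees
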