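"""Shared fixtures and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from genecontent.treeio import Phylogeny, parse_tree
from genecontent.synthetic_data import simulate_tree


def brute_force_wagner_cost(tree: Phylogeny, tip_counts, max_state=None) -> int:
    """Exhaustive minimum of total |parent-child| change over all internal
    assignments — the independent oracle for the parsimony DP."""
    if max_state is None:
        max_state = max(tip_counts.values())
    internals = tree.internal_nodes
    branches = tree.branches()
    best = None
    for assign in itertools.product(range(max_state + 1), repeat=len(internals)):
        states = dict(zip(internals, assign))
        states.update(tip_counts)
        cost = sum(abs(states[c] - states[p]) for p, c in branches)
        if best is None or cost < best:
            best = cost
    return best


def random_small_instance(rng, max_tips=6, max_count=4):
    """A random dated tree with <= max_tips tips and random tip counts."""
    n_tips = int(rng.integers(2, max_tips + 1))
    tree = simulate_tree(n_tips, 100.0, seed=int(rng.integers(0, 2**31 - 1)))
    tip_counts = {t: int(rng.integers(0, max_count + 1)) for t in tree.tips}
    return tree, tip_counts


@pytest.fixture
def cherry3():
    """((A,B),C) with unit-ish durations; internal nodes 0 (root) and 1."""
    return parse_tree("((A:1,B:1)1:1,C:2);")


@pytest.fixture
def quartet():
    """((A,B),(C,D)); internal nodes named ab, cd, root r."""
    return parse_tree("((A:1,B:1)ab:1,(C:1,D:1)cd:1)r;")


@pytest.fixture
def star5():
    """Root with five tip children (five branches)."""
    return parse_tree("(A:1,B:1,C:1,D:1,E:1)r;")


@pytest.fixture
def caterpillar4():
    """(((A,B),C),D) ultrametric: internal ages 10, 20, 30."""
    return parse_tree("(((A:10,B:10)n2:10,C:20)n1:10,D:30)n0;")
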