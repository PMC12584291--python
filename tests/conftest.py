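"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms: Shapley
values are computed by exhaustive subset enumeration, and eating-occasion
grouping by pairwise union-find clustering, so they can serve as independent
references for the production implementations.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest

from eodiet.synthetic_cohort import (
    cohort_to_frame,
    default_truth,
    generate_cohort,
    generate_occasions,
)


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(40, seed=11)


@pytest.fixture(scope="session")
def small_occasions(small_cohort):
    occ = generate_occasions(small_cohort, default_truth(), seed=12)
    return occ.merge(cohort_to_frame(small_cohort), on="participant_id")


# ------------------------------------------------- exact Shapley oracle

def tree_conditional_expectation(tree, x: np.ndarray, known: set,
                                 leaf_values: np.ndarray | None = None) -> float:
    """E[f(x)] when only the features in ``known`` are fixed.

    Descends the tree; at splits on unknown features both children contribute
    weighted by their training cover (the value function the path-dependent
    attribution is defined against).
    """
    cl, cr = tree.children_left, tree.children_right
    feat, thr, w = tree.feature, tree.threshold, tree.weighted_n_node_samples
    v = leaf_values if leaf_values is not None else tree.value[:, 0, 0]

    def rec(n: int) -> float:
        if cl[n] < 0:
            return float(v[n])
        if feat[n] in known:
            return rec(cl[n] if x[feat[n]] <= thr[n] else cr[n])
        return (w[cl[n]] * rec(cl[n]) + w[cr[n]] * rec(cr[n])) / w[n]

    return rec(0)


def brute_force_shapley(tree, x: np.ndarray, n_features: int,
                        leaf_values: np.ndarray | None = None) -> np.ndarray:
    """Exhaustive Shapley values over all 2^p coalitions (p <= ~12)."""
    phi = np.zeros(n_features)
    feats = list(range(n_features))
    for i in feats:
        rest = [j for j in feats if j != i]
        for r in range(len(rest) + 1):
            for S in combinations(rest, r):
                weight = factorial(len(S)) * factorial(n_features - len(S) - 1) \
                    / factorial(n_features)
                with_i = tree_conditional_expectation(tree, x, set(S) | {i}, leaf_values)
                without = tree_conditional_expectation(tree, x, set(S), leaf_values)
                phi[i] += weight * (with_i - without)
    return phi


# ------------------------------------- brute-force EO clustering oracle

def union_find_partition(timestamps: np.ndarray, window: float) -> list[list[int]]:
    """Single-linkage clusters of item indices via pairwise union-find."""
    n = len(timestamps)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if abs(timestamps[i] - timestamps[j]) <= window:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values())
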