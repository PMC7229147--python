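"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's fast paths: likelihoods by
exhaustive enumeration over internal-state assignments, Otsu by scanning all
256 thresholds, entropy by a naive double loop. They are the ground truth the
implementations are tested against.
"""

import itertools

import numpy as np
import pytest

from webfoot import CharacterStateMap, MkModel, read_newick, transition_matrix


# --------------------------------------------------------------------------
# likelihood / marginal oracles (enumeration over unobserved node states)


def _free_and_observed(tree, states):
    free = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    observed = {}
    for v in tree.tips:
        s = states[tree.labels[v]]
        if s is None:
            free.append(int(v))
        else:
            observed[int(v)] = int(s)
    return free, observed


def enum_likelihood(tree, states, model):
    """P(data) by brute force over all assignments of unobserved nodes."""
    k = model.k
    free, observed = _free_and_observed(tree, states)
    P = {v: transition_matrix(model, float(tree.branch_lengths[v])) for v in range(tree.n_nodes)}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(free)):
        amap = dict(zip(free, assign))
        amap.update(observed)
        p = 1.0 / k
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                p *= P[v][amap[int(tree.parent[v])], amap[v]]
        total += p
    return total


def enum_loglik(tree, states, model):
    return float(np.log(enum_likelihood(tree, states, model)))


def enum_marginals(tree, states, model):
    """Per-node posterior state masses by Bayes rule over the enumeration."""
    k = model.k
    free, observed = _free_and_observed(tree, states)
    P = {v: transition_matrix(model, float(tree.branch_lengths[v])) for v in range(tree.n_nodes)}
    mass = np.zeros((tree.n_nodes, k))
    for assign in itertools.product(range(k), repeat=len(free)):
        amap = dict(zip(free, assign))
        amap.update(observed)
        p = 1.0 / k
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                p *= P[v][amap[int(tree.parent[v])], amap[v]]
        for v, s in amap.items():
            mass[v, s] += p
    return mass / mass.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# imaging oracles


def brute_otsu(image):
    """First argmax of between-class variance over all 256 split points."""
    flat = np.asarray(image).ravel().astype(float)
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def naive_entropy(mask, w_max):
    """The quadruple sum, literally, skipping zero-distance pairs.

    Terms are accumulated with math.fsum so the oracle's own rounding cannot
    mask a real discrepancy.
    """
    import math

    coords = np.argwhere(np.asarray(mask, dtype=bool))
    terms = []
    for i in range(coords.shape[0]):
        for j in range(coords.shape[0]):
            if i == j:
                continue
            d = np.hypot(*(coords[i] - coords[j]).astype(float))
            terms.append(np.log(d / w_max))
    return math.fsum(terms)


def naive_entropy_points(points, w_max):
    import math

    pts = np.asarray(points, dtype=float)
    terms = []
    for i in range(pts.shape[0]):
        for j in range(pts.shape[0]):
            if i != j:
                terms.append(np.log(np.hypot(*(pts[i] - pts[j])) / w_max))
    return math.fsum(terms)


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture
def cherry():
    return read_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:1);")


@pytest.fixture
def three_tip_states():
    return CharacterStateMap({"A": 0, "B": 0, "C": 1}, 2)


@pytest.fixture
def mk2():
    return MkModel(2, 0.3)


def random_small_tree_and_states(rng, max_tips=5, max_k=3, allow_missing=True):
    """A random small test case for enumeration comparisons."""
    from webfoot.synth import generate_random_tree

    n = int(rng.integers(2, max_tips + 1))
    k = int(rng.integers(2, max_k + 1))
    tree = generate_random_tree(n, int(rng.integers(2**31)))
    states = {}
    for lb in tree.tip_labels:
        if allow_missing and rng.random() < 0.15:
            states[lb] = None
        else:
            states[lb] = int(rng.integers(k))
    if all(s is None for s in states.values()):
        states[tree.tip_labels[0]] = 0
    rate = float(rng.uniform(0.01, 2.0))
    return tree, CharacterStateMap(states, k), MkModel(k, rate)
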