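"""The symmetric k-state Markov (Mk) model and its tree likelihood.

The Mk ("Mk1") model has a single free parameter, the per-pair substitution
rate r: the rate matrix has off-diagonals r and diagonal -(k-1)r, so its
transition probabilities have the closed form

    P_ii(t) = 1/k + (k-1)/k * exp(-k r t)
    P_ij(t) = 1/k -   1/k  * exp(-k r t)      (i != j)

Likelihoods use Felsenstein's pruning recursion, vectorised across characters
and scaled per node to avoid underflow. The root prior is uniform 1/k (the Mk
stationary distribution). Marginal ancestral state probabilities combine the
downward conditional likelihoods with an upward pass carrying the rest of the
tree, which is equivalent to re-rooting at each node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .characters import CharacterStateMap
from .errors import EstimationError, NumericalError, ValidationError
from .tree import PhyloTree

__all__ = [
    "MkModel",
    "AncestralReconstruction",
    "transition_matrix",
    "tree_log_likelihood",
    "multi_log_likelihood",
    "fit_rate",
    "marginal_asr",
]

DEFAULT_RATE_BOUNDS = (1e-8, 100.0)
DEFAULT_RATE_TOL = 1e-8


@dataclass(frozen=True)
class MkModel:
    """State count k (>= 2) and symmetric per-pair rate r (>= 0, per unit branch)."""

    k: int
    rate: float

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError(f"k must be >= 2, got {self.k}")
        if self.rate < 0:
            raise ValidationError(f"rate must be >= 0, got {self.rate}")

    def transition_matrix(self, t: float) -> np.ndarray:
        return transition_matrix(self, t)

    @property
    def rate_matrix(self) -> np.ndarray:
        Q = np.full((self.k, self.k), self.rate)
        np.fill_diagonal(Q, -(self.k - 1) * self.rate)
        return Q


def transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """Closed-form Mk transition probabilities over a branch of length t."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    k = model.k
    e = np.exp(-k * model.rate * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, (1.0 + (k - 1) * e) / k)
    return P


def _validate_states(tree: PhyloTree, states: CharacterStateMap) -> None:
    missing = [tree.labels[v] for v in tree.tips if tree.labels[v] not in states]
    if missing:
        raise ValidationError(f"tips absent from state map: {missing}")


def _tip_partials(tree: PhyloTree, chars, k: int) -> np.ndarray:
    """Conditional likelihood array (n_nodes, k, n_chars); tips one-hot,
    missing tips all-ones."""
    m = len(chars)
    down = np.zeros((tree.n_nodes, k, m))
    for tip in tree.tips:
        label = tree.labels[tip]
        for j, ch in enumerate(chars):
            s = ch[label]
            if s is None:
                down[tip, :, j] = 1.0
            else:
                down[tip, int(s), j] = 1.0
    return down


def _down_pass(tree: PhyloTree, down: np.ndarray, model: MkModel):
    """Fill internal rows of ``down`` (scaled so each node's max is 1) and
    return per-character log-likelihoods under the uniform root prior."""
    k, m = down.shape[1], down.shape[2]
    log_scale = np.zeros(m)
    dead = np.zeros(m, dtype=bool)  # characters with zero likelihood
    P_cache: dict = {}
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        L = np.ones((k, m))
        for c in kids:
            t = float(tree.branch_lengths[c])
            P = P_cache.get(t)
            if P is None:
                P = P_cache.setdefault(t, transition_matrix(model, t))
            L *= P @ down[c]
        mx = L.max(axis=0)
        zero = mx == 0.0
        dead |= zero
        safe = np.where(zero, 1.0, mx)
        down[v] = L / safe
        log_scale += np.log(safe)
    prior = np.full(k, 1.0 / k)
    root_like = prior @ down[tree.root]
    dead |= root_like == 0.0
    with np.errstate(divide="ignore"):
        ll = np.log(np.where(dead, 1.0, root_like)) + log_scale
    ll[dead] = -np.inf
    return ll, down


def multi_log_likelihood(tree: PhyloTree, chars, model: MkModel) -> np.ndarray:
    """Log-likelihood of each character in ``chars`` (one pruning pass, shared
    transition matrices)."""
    for ch in chars:
        _validate_states(tree, ch)
    down = _tip_partials(tree, chars, model.k)
    ll, _ = _down_pass(tree, down, model)
    return ll


def tree_log_likelihood(tree: PhyloTree, states: CharacterStateMap, model: MkModel) -> float:
    """Felsenstein pruning log-likelihood of one character."""
    return float(multi_log_likelihood(tree, [states], model)[0])


def fit_rate(
    tree: PhyloTree,
    chars,
    k: int,
    bounds=DEFAULT_RATE_BOUNDS,
    tol: float = DEFAULT_RATE_TOL,
):
    """Maximum-likelihood estimate of the single Mk rate.

    Bounded 1-D maximisation of the summed log-likelihood over ``chars`` on
    ``bounds`` (default [1e-8, 100]) to absolute tolerance ``tol`` on r; the
    boundary r=0 is checked explicitly so constant data returns exactly 0.

    Returns ``(MkModel(k, r_hat), max_log_likelihood)``.
    """
    chars = list(chars)
    if not chars:
        raise EstimationError("at least one character is required")
    for ch in chars:
        _validate_states(tree, ch)
    if all(ch.n_observed == 0 for ch in chars):
        raise EstimationError("all characters are entirely missing; rate is unidentifiable")

    tip_base = _tip_partials(tree, chars, k)

    def total_ll(r: float) -> float:
        ll, _ = _down_pass(tree, tip_base.copy(), MkModel(k, r))
        return float(ll.sum())

    # The likelihood flattens into a long plateau at large r (stationary
    # limit), so a linear golden-section over [lo, hi] can stall there.
    # Locate the optimum on a log-rate scale first, then polish linearly.
    lo, hi = bounds
    coarse = minimize_scalar(
        lambda u: -total_ll(np.exp(u)),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    r0 = float(np.exp(coarse.x))
    res = minimize_scalar(
        lambda r: -total_ll(r),
        bounds=(max(lo, r0 / 4.0), min(hi, r0 * 4.0)),
        method="bounded",
        options={"xatol": tol},
    )
    r_hat, best = float(res.x), -float(res.fun)
    ll_zero = total_ll(0.0)
    if ll_zero >= best:
        r_hat, best = 0.0, ll_zero
    if not np.isfinite(best):
        raise EstimationError("log-likelihood is -inf over the whole bracket")
    return MkModel(k, r_hat), best


@dataclass
class AncestralReconstruction:
    """Marginal state probabilities per node, plus the model they came from.

    ``node_probabilities`` maps internal-node index -> length-k probability
    vector (each sums to 1); ``tip_probabilities`` gives the same for tips
    (one-hot for observed tips, informative for missing ones).
    """

    tree: PhyloTree
    k: int
    rate: float
    log_likelihood: float
    node_probabilities: dict
    tip_probabilities: dict

    def probabilities(self, node: int) -> np.ndarray:
        if node in self.node_probabilities:
            return self.node_probabilities[node]
        return self.tip_probabilities[node]

    def all_probabilities(self) -> dict:
        return {**self.tip_probabilities, **self.node_probabilities}


def marginal_asr(tree: PhyloTree, states: CharacterStateMap, model: MkModel) -> AncestralReconstruction:
    """Marginal (per-node) ancestral state probabilities.

    Down pass: conditional likelihoods of each subtree. Up pass: for a child c
    of u, ``up[c] = P(t_c)^T @ (up[u] * prod(sibling contributions))``. The
    marginal at any node is ``up * down`` renormalised; at the root this is
    prior times root conditionals, renormalised.
    """
    _validate_states(tree, states)
    k = model.k
    down3 = _tip_partials(tree, [states], k)
    ll, down3 = _down_pass(tree, down3, model)
    if not np.isfinite(ll[0]):
        raise NumericalError("zero likelihood: data impossible under this model")
    D = down3[:, :, 0]

    P_cache: dict = {}

    def P_of(c):
        t = float(tree.branch_lengths[c])
        P = P_cache.get(t)
        if P is None:
            P = P_cache.setdefault(t, transition_matrix(model, t))
        return P

    up = np.zeros((tree.n_nodes, k))
    up[tree.root] = 1.0 / k
    for u in tree.preorder:
        kids = tree.children[u]
        if not kids:
            continue
        M = np.stack([P_of(c) @ D[c] for c in kids])  # (n_children, k)
        nc = len(kids)
        prefix = np.ones((nc + 1, k))
        for i in range(nc):
            prefix[i + 1] = prefix[i] * M[i]
        suffix = np.ones((nc + 1, k))
        for i in range(nc - 1, -1, -1):
            suffix[i] = suffix[i + 1] * M[i]
        for i, c in enumerate(kids):
            excl = prefix[i] * suffix[i + 1]
            vec = P_of(c).T @ (up[u] * excl)
            s = vec.sum()
            if s > 0:
                vec = vec / s
            up[c] = vec

    node_probs, tip_probs = {}, {}
    for v in range(tree.n_nodes):
        p = up[v] * D[v]
        total = p.sum()
        if total <= 0:
            raise NumericalError(f"zero marginal mass at node {v}")
        p = p / total
        (tip_probs if tree.is_tip(v) else node_probs)[int(v)] = p
    return AncestralReconstruction(
        tree=tree,
        k=k,
        rate=model.rate,
        log_likelihood=float(ll[0]),
        node_probabilities=node_probs,
        tip_probabilities=tip_probs,
    )
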