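"""Independent brute-force oracles for the DEC likelihood and posteriors.

The likelihood oracle sums explicitly over every assignment of ranges to
internal nodes, with the per-node cladogenetic weight obtained by direct
enumeration of daughter events and explicit ``expm`` branch matrices.
It shares no code path with the pruning engine beyond the model
definition itself.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from decranges.cladogenesis import enumerate_daughter_events
from decranges.likelihood import TreeIndex


def _branch_matrices(idx: TreeIndex, qs) -> dict[int, np.ndarray]:
    """Explicit P over each branch: P_oldest @ ... @ P_youngest."""
    S = qs[0].shape[0]
    out = {}
    for i in range(len(idx.nodes)):
        P = np.eye(S)
        for ei, dt in reversed(idx.segments[i]):  # oldest segment first
            P = P @ expm(qs[ei] * dt)
        out[i] = P
    return out


def brute_force_history_sums(tree, tips, model, params):
    """Joint likelihood contribution of every internal-range assignment.

    Returns ``(internal_nodes, assignments, weights, idx)`` where
    ``weights[k]`` is the summed probability of all histories whose
    internal nodes carry ``assignments[k]``.
    """
    space = model.space
    idx = TreeIndex(tree, model.stratification())
    qs = model.q_matrices(params)
    Pb = _branch_matrices(idx, qs)
    n = len(idx.nodes)
    internal = [i for i in range(n) if not idx.is_leaf[i]]
    tip_state = {
        i: space.index(tips[idx.taxon_label[i]])
        for i in range(n)
        if idx.is_leaf[i]
    }
    nonnull = [j for j, s in enumerate(space.states) if not s.is_null]
    assignments = list(itertools.product(nonnull, repeat=len(internal)))
    weights = np.zeros(len(assignments))
    for k, assign in enumerate(assignments):
        amap = dict(zip(internal, assign))
        end = {**tip_state, **amap}
        prob = 1.0
        for u in internal:
            A = space.states[amap[u]]
            l, r = idx.children[u]
            w = 0.0
            for ev in enumerate_daughter_events(A, space.max_size):
                w += (
                    ev.prob
                    * Pb[l][space.index(ev.left), end[l]]
                    * Pb[r][space.index(ev.right), end[r]]
                )
            prob *= w
        weights[k] = prob
    return internal, assignments, weights, idx


def brute_force_loglik(tree, tips, model, params, root="sum"):
    """Log-likelihood by explicit summation over all internal assignments."""
    _, _, weights, _ = brute_force_history_sums(tree, tips, model, params)
    total = weights.sum()
    if root == "uniform":
        n_nonnull = sum(1 for s in model.space.states if not s.is_null)
        total /= n_nonnull
    return float(np.log(total))


def brute_force_marginals(tree, tips, model, params):
    """Posterior range probabilities per internal node, by enumeration.

    Returns a dict mapping postorder node index -> probability vector
    over the range space.
    """
    space = model.space
    internal, assignments, weights, idx = brute_force_history_sums(
        tree, tips, model, params
    )
    total = weights.sum()
    post = {u: np.zeros(len(space)) for u in internal}
    for assign, w in zip(assignments, weights):
        for u, s in zip(internal, assign):
            post[u][s] += w
    for u in internal:
        post[u] /= total
    return post
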