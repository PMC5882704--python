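"""Brute-force likelihood and marginal oracles for tiny trees.

The oracle enumerates every joint assignment of ancestral states and
cladogenetic events explicitly and multiplies exp(Q t) entries computed
directly with scipy's expm — no pruning, no caching, no vector algebra —
so it is an independent check of the production likelihood path.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from fossilrange.model import (ModelParams, ModelSpec, StateSpace, Stratum,
                               build_q, cladogenesis_table)


def _branch_matrix(child_age, parent_age, strata, Qs):
    """expm product over the strata crossed by a branch (oldest first)."""
    P = np.eye(Qs[0].shape[0])
    for k, s in enumerate(strata):  # oldest stratum first
        lo = max(child_age, s.younger)
        hi = min(parent_age, s.older)
        if hi > lo:
            P = P @ scipy.linalg.expm(Qs[k] * (hi - lo))
    return P


def brute_force_loglik(tree, geo, spec: ModelSpec, params: ModelParams,
                       strata) -> float:
    """Exhaustive-enumeration log-likelihood for trees of a few tips."""
    space = StateSpace(geo.areas, spec.max_range_size)
    Qs = [build_q(space, params, s) for s in strata]
    idx = space.index

    def below(node, top_state):
        """P(data below node | branch above node starts in top_state)."""
        P = _branch_matrix(node.age, node.parent.age, strata, Qs)
        total = 0.0
        for end_state in space.states:
            pij = P[idx[top_state], idx[end_state]]
            if pij == 0.0:
                continue
            total += pij * at_node(node, end_state)
        return total

    def at_node(node, state):
        """P(data below node | node in `state` before its cladogenesis)."""
        if node.is_leaf:
            return 1.0 if state == geo.ranges[node.label] else 0.0
        if state == 0:
            return 0.0
        total = 0.0
        for l, r, p in cladogenesis_table(spec, state, space, params):
            total += p * below(node.children[0], l) * below(node.children[1],
                                                            r)
        return total

    prior = 1.0 / (space.nstates - 1)
    like = sum(prior * at_node(tree.root, s) for s in space.states if s != 0)
    return np.log(like) if like > 0 else -np.inf


def brute_force_marginals(tree, geo, spec, params, strata):
    """Joint-enumeration marginal node-state probabilities.

    Enumerates every assignment of pre-cladogenesis states to the internal
    nodes, scoring each by summing over the cladogenetic events compatible
    with it.  Returns {node id: {state mask: probability}}.
    """
    space = StateSpace(geo.areas, spec.max_range_size)
    Qs = [build_q(space, params, s) for s in strata]
    idx = space.index
    internals = [n for n in tree.preorder() if not n.is_leaf]

    def score(assign):
        """Joint probability of data with internal states fixed."""
        def below(node, top_state):
            P = _branch_matrix(node.age, node.parent.age, strata, Qs)
            if node.is_leaf:
                return P[idx[top_state], idx[geo.ranges[node.label]]]
            end = assign[id(node)]
            return P[idx[top_state], idx[end]] * at_node(node, end)

        def at_node(node, state):
            total = 0.0
            for l, r, p in cladogenesis_table(spec, state, space, params):
                total += p * below(node.children[0], l) \
                    * below(node.children[1], r)
            return total

        root_state = assign[id(tree.root)]
        prior = 1.0 / (space.nstates - 1)
        return prior * at_node(tree.root, root_state)

    from itertools import product
    non_null = [s for s in space.states if s != 0]
    weights = {id(n): {} for n in internals}
    total = 0.0
    for combo in product(non_null, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        w = score(assign)
        total += w
        for n, s in zip(internals, combo):
            weights[id(n)][s] = weights[id(n)].get(s, 0.0) + w
    return {k: {s: v / total for s, v in d.items()}
            for k, d in weights.items()}
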