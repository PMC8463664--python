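"""Independent brute-force oracles for CTMC likelihoods on small trees.

These enumerate all internal-node state assignments and use scipy's ``expm``
directly, sharing no code with the package's pruning engine.
"""

import itertools

import numpy as np
from scipy.linalg import expm


def enum_loglik(tree, Q, tip_partials, root_prior):
    """Sum over all internal-node state assignments of the joint probability."""
    k = Q.shape[0]
    P = [expm(Q * t) for t in tree.lengths]
    internal = [i for i in range(tree.n_nodes) if i >= tree.n_tips]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        prob = root_prior[st[tree.root]]
        for node in range(tree.n_nodes):
            if node == tree.root:
                continue
            pa = st[tree.parent[node]]
            if node < tree.n_tips:
                prob *= sum(P[node][pa, s] * tip_partials[node, s] for s in range(k))
            else:
                prob *= P[node][pa, st[node]]
        total += prob
    return np.log(total)


def enum_marginals(tree, Q, tip_partials, root_prior):
    """Brute-force conditional state probabilities at every internal node."""
    k = Q.shape[0]
    P = [expm(Q * t) for t in tree.lengths]
    internal = [i for i in range(tree.n_nodes) if i >= tree.n_tips]
    joint = {}
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        prob = root_prior[st[tree.root]]
        for node in range(tree.n_nodes):
            if node == tree.root:
                continue
            pa = st[tree.parent[node]]
            if node < tree.n_tips:
                prob *= sum(P[node][pa, s] * tip_partials[node, s] for s in range(k))
            else:
                prob *= P[node][pa, st[node]]
        joint[assign] = prob
    total = sum(joint.values())
    out = {}
    for i, node in enumerate(internal):
        out[node] = np.array(
            [sum(p for a, p in joint.items() if a[i] == s) / total for s in range(k)]
        )
    return out
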