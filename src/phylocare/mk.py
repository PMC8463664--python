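"""Mk (equal-rates) models on trees: pruning likelihood, ML fit, marginal ASR.

The continuous-time Markov chain machinery here is shared with the 4-state
correlated-evolution models in :mod:`phylocare.pagel`: a tree is compiled once
into a level schedule so Felsenstein's pruning pass runs as a handful of
batched numpy operations per level rather than a Python loop per node.
Underflow is controlled by per-node rescaling of partial likelihoods with
accumulated log-scalers.

The equal-rates (ER) Mk model has a single transition rate ``q`` shared by all
ordered state pairs; its transition probabilities have the closed form
``P(t) = 1/k + (I - 1/k) * exp(-k q t)``, and its stationary (and default
root) distribution is uniform over the ``k`` states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .trees import PhyloTree

__all__ = [
    "MkModel",
    "MkFit",
    "AsrResult",
    "mk_loglik",
    "fit_er",
    "marginal_asr",
    "tip_partials_from_states",
]

MISSING = -1  # sentinel for an unobserved tip state


# ---------------------------------------------------------------------------
# pruning schedule: compile a tree into level-batched arrays
# ---------------------------------------------------------------------------


class PruningSchedule:
    """Level-order batching of a tree's internal nodes.

    Level ``h`` contains internal nodes whose longest path to a descendant tip
    has ``h`` edges, so all children of a level-``h`` node live in levels
    ``< h`` and are already evaluated when the level is processed.  For each
    level we store the node indices, the flattened child indices sorted by
    parent, and ``reduceat`` offsets for the per-parent product.
    """

    def __init__(self, tree: PhyloTree):
        self.tree = tree
        n = tree.n_nodes
        height = np.zeros(n, dtype=np.int64)
        for node in tree.postorder:
            if tree.children[node]:
                height[node] = 1 + max(height[c] for c in tree.children[node])
        self.levels = []
        max_h = int(height[tree.root]) if n > 1 else 0
        for h in range(1, max_h + 1):
            nodes = np.flatnonzero(height == h)
            nodes = nodes[nodes >= tree.n_tips]
            if nodes.size == 0:
                continue
            child_idx = []
            offsets = [0]
            for nd in nodes:
                child_idx.extend(tree.children[nd])
                offsets.append(len(child_idx))
            self.levels.append(
                (
                    nodes,
                    np.asarray(child_idx, dtype=np.int64),
                    np.asarray(offsets[:-1], dtype=np.int64),
                )
            )


def _schedule(tree: PhyloTree) -> PruningSchedule:
    sched = tree._cache.get("pruning_schedule")
    if sched is None:
        sched = PruningSchedule(tree)
        tree._cache["pruning_schedule"] = sched
    return sched


def prune_loglik(
    tree: PhyloTree,
    P: np.ndarray,
    tip_partials: np.ndarray,
    root_prior: np.ndarray,
) -> float:
    """Felsenstein pruning log-likelihood.

    Parameters
    ----------
    P : (n_nodes, k, k) transition probability matrices for the edge above
        each node (the root's entry is ignored).
    tip_partials : (n_tips, k) conditional likelihood vectors at the tips
        (one-hot for observed states, all-ones for missing).
    root_prior : (k,) probability vector weighting the root state.
    """
    k = tip_partials.shape[1]
    partial = np.zeros((tree.n_nodes, k))
    partial[: tree.n_tips] = tip_partials
    log_scale = 0.0
    for nodes, child_idx, offsets in _schedule(tree).levels:
        msgs = (P[child_idx] @ partial[child_idx][:, :, None])[:, :, 0]
        prod = np.multiply.reduceat(msgs, offsets, axis=0)
        # rescale each node's partial to max 1, accumulating the log-scaler
        m = prod.max(axis=1, keepdims=True)
        if m.min() <= 0:
            return -np.inf
        partial[nodes] = prod / m
        log_scale += float(np.log(m).sum())
    root_part = partial[tree.root]
    like = float(root_prior @ root_part)
    if like <= 0:
        return -np.inf
    return np.log(like) + log_scale


# ---------------------------------------------------------------------------
# ER model
# ---------------------------------------------------------------------------


@dataclass
class MkModel:
    """Equal-rates Mk model: ``k`` states, one shared rate ``q`` (per unit time)."""

    k: int
    q: float
    root_prior: np.ndarray | None = None

    def __post_init__(self):
        if self.q < 0:
            raise ValueError("rate q must be non-negative")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.root_prior is None:
            self.root_prior = np.full(self.k, 1.0 / self.k)
        else:
            self.root_prior = np.asarray(self.root_prior, dtype=float)
            if self.root_prior.shape != (self.k,) or not np.isclose(
                self.root_prior.sum(), 1.0
            ):
                raise ValueError("root_prior must be a length-k probability vector")

    def rate_matrix(self) -> np.ndarray:
        Q = np.full((self.k, self.k), self.q)
        np.fill_diagonal(Q, -(self.k - 1) * self.q)
        return Q

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """Closed-form ER transition probabilities for a vector of branch lengths."""
        k, q = self.k, self.q
        e = np.exp(-k * q * np.asarray(lengths, dtype=float))  # (n,)
        P = (1.0 - e)[:, None, None] / k * np.ones((k, k))
        P[:, np.arange(k), np.arange(k)] += e[:, None]
        return P


def tip_partials_from_states(states: np.ndarray, k: int) -> np.ndarray:
    """One-hot tip partials; ``MISSING`` (or negative / nan) marginalises to ones."""
    states = np.asarray(states)
    n = states.shape[0]
    part = np.ones((n, k))
    if np.issubdtype(states.dtype, np.floating):
        obs = ~np.isnan(states)
        idx = states[obs].astype(np.int64)
    else:
        obs = states >= 0
        idx = states[obs].astype(np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= k):
        raise ValueError(f"tip states must lie in 0..{k - 1}")
    rows = np.flatnonzero(obs)
    part[rows] = 0.0
    part[rows, idx] = 1.0
    return part


def _check_states(tree: PhyloTree, states) -> np.ndarray:
    states = np.asarray(states, dtype=float)
    if states.shape[0] != tree.n_tips:
        raise ValueError(
            f"need one state per tip ({tree.n_tips}), got {states.shape[0]}"
        )
    if not np.any(~np.isnan(states)):
        raise ValueError("no observed tip states")
    return states


def mk_loglik(tree: PhyloTree, states, model: MkModel) -> float:
    """Log-likelihood of tip *states* under an ER Mk model.

    Missing states (nan or negative) contribute all-ones partial vectors, i.e.
    are marginalised rather than dropped.
    """
    states = _check_states(tree, states)
    P = model.transition_matrices(tree.lengths)
    tp = tip_partials_from_states(states, model.k)
    return prune_loglik(tree, P, tp, model.root_prior)


@dataclass
class MkFit:
    """Maximum-likelihood ER fit."""

    model: MkModel
    loglik: float
    at_boundary: bool
    monomorphic: bool


_Q_LO, _Q_HI = 1e-8, 1e3


def fit_er(tree: PhyloTree, states, k: int, root_prior=None) -> MkFit:
    """Maximise the ER likelihood over ``q`` on a log-scale bounded interval.

    A coarse log-grid scan seeds a bounded 1-D refinement, which is robust to
    the flat ridges that arise with sparse data.  Monomorphic data drive the
    rate to the lower bound; this is flagged rather than hidden.
    """
    states = _check_states(tree, states)
    observed = states[~np.isnan(states)].astype(int)
    monomorphic = np.unique(observed).size < 2

    def negloglik(log_q):
        model = MkModel(k=k, q=float(np.exp(log_q)), root_prior=root_prior)
        return -mk_loglik(tree, states, model)

    grid = np.linspace(np.log(_Q_LO), np.log(_Q_HI), 31)
    vals = [negloglik(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    lo = max(np.log(_Q_LO), g0 - 1.5)
    hi = min(np.log(_Q_HI), g0 + 1.5)
    res = minimize_scalar(negloglik, bounds=(lo, hi), method="bounded")
    q_hat = float(np.exp(res.x))
    at_boundary = q_hat <= _Q_LO * 10 or q_hat >= _Q_HI / 10
    model = MkModel(k=k, q=q_hat, root_prior=root_prior)
    return MkFit(
        model=model,
        loglik=float(-res.fun),
        at_boundary=at_boundary or monomorphic,
        monomorphic=monomorphic,
    )


# ---------------------------------------------------------------------------
# marginal ancestral state reconstruction
# ---------------------------------------------------------------------------


@dataclass
class AsrResult:
    """Marginal ancestral state probabilities at internal nodes.

    ``node_probs`` is indexed by node id (tips carry their observed one-hot
    vector, renormalised over compatible states when missing).
    """

    node_probs: np.ndarray  # (n_nodes, k)
    q_hat: float
    loglik: float
    internal_nodes: np.ndarray


def marginal_asr(tree: PhyloTree, states, model: MkModel) -> AsrResult:
    """Marginal posterior state probabilities at every node (up-down pass).

    The down (pruning) pass computes the conditional likelihood of the data
    below each node; the up pass propagates the likelihood of everything
    outside the subtree.  Their product, normalised, is the marginal posterior
    given *all* tips — the re-rooting reconstruction.
    """
    states = _check_states(tree, states)
    k = model.k
    P = model.transition_matrices(tree.lengths)
    tp = tip_partials_from_states(states, k)
    n = tree.n_nodes
    down = np.zeros((n, k))
    down[: tree.n_tips] = tp
    # plain per-node pass (ASR is run once per trait; clarity over speed here)
    for node in tree.postorder:
        if node < tree.n_tips:
            continue
        part = np.ones(k)
        for c in tree.children[node]:
            part = part * (P[c] @ down[c])
        s = part.max()
        if s <= 0:
            raise ValueError("zero partial likelihood; data incompatible with model")
        down[node] = part / s

    up = np.zeros((n, k))
    up[tree.root] = model.root_prior
    for node in tree.postorder[::-1]:
        if node < tree.n_tips:
            continue
        msgs = {c: P[c] @ down[c] for c in tree.children[node]}
        for c in tree.children[node]:
            outer = up[node].copy()
            for s_ in tree.children[node]:
                if s_ != c:
                    outer = outer * msgs[s_]
            vec = P[c].T @ outer
            m = vec.max()
            up[c] = vec / m if m > 0 else vec

    probs = up * down
    norm = probs.sum(axis=1, keepdims=True)
    if np.any(norm <= 0):
        raise ValueError("degenerate marginal probabilities")
    probs = probs / norm
    loglik = mk_loglik(tree, states, model)
    internal = np.asarray(
        [nd for nd in tree.postorder if nd >= tree.n_tips], dtype=np.int64
    )
    return AsrResult(
        node_probs=probs, q_hat=model.q, loglik=loglik, internal_nodes=internal
    )
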