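"""Phylogenetic trees: Newick I/O, ultrametricity checks, Brownian covariance, pruning.

Trees are rooted, branch lengths are in time units (e.g. millions of years) and
must be present on every non-root edge.  Internally a :class:`PhyloTree` stores
flat parent/length arrays with tips occupying indices ``0 .. n_tips-1``, which is
what the likelihood machinery in :mod:`phylocare.mk` consumes directly.  Parsing
and serialisation go through dendropy.
"""

from __future__ import annotations

import io
import sys
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "NewickError",
    "normalize_name",
    "read_newick",
    "parse_newick",
    "collapse_zero_internal_branches",
    "write_newick",
    "vcv",
    "prune_to_taxa",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or missing branch lengths."""


def normalize_name(name: str) -> str:
    """Normalise a taxon label: strip whitespace, spaces -> underscores.

    Matching between tree tips and trait-table species is case-sensitive after
    this normalisation; mismatches are reported by callers, never dropped.
    """
    return name.strip().replace(" ", "_")


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance: C[i, j] = root-to-MRCA depth of taxa i, j."""

    taxa: list[str]
    matrix: np.ndarray

    def submatrix(self, taxa) -> "PhyloCovariance":
        idx = [self.taxa.index(normalize_name(t)) for t in taxa]
        return PhyloCovariance(
            [self.taxa[i] for i in idx], self.matrix[np.ix_(idx, idx)].copy()
        )


class PhyloTree:
    """Rooted tree with branch lengths, tips at indices ``0 .. n_tips-1``.

    Parameters
    ----------
    parent : integer array, parent index per node (-1 for the root)
    lengths : float array, length of the edge above each node (0 for the root)
    tip_labels : labels for nodes ``0 .. n_tips-1``
    """

    def __init__(self, parent, lengths, tip_labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.tip_labels = [normalize_name(t) for t in tip_labels]
        n = self.parent.size
        if self.lengths.size != n:
            raise ValueError("parent and lengths must have equal size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if np.any(self.lengths < 0):
            bad = np.flatnonzero(self.lengths < 0)
            raise ValueError(f"negative branch lengths at nodes {bad.tolist()}")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dup = sorted(
                {t for t in self.tip_labels if self.tip_labels.count(t) > 1}
            )
            raise ValueError(f"duplicate tip labels after normalization: {dup}")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        self.n_tips = len(self.tip_labels)
        for i in range(self.n_tips):
            if self.children[i]:
                raise ValueError(f"node {i} is labelled a tip but has children")
        self.postorder = self._compute_postorder()
        self._cache: dict = {}

    # -- construction -------------------------------------------------

    def _compute_postorder(self) -> np.ndarray:
        order = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return np.asarray(order, dtype=np.int64)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        leaves = list(dtree.leaf_node_iter())
        internal = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
        index = {}
        labels = []
        for i, nd in enumerate(leaves):
            index[nd] = i
            if nd.taxon is None or nd.taxon.label is None:
                raise NewickError("unlabelled tip in tree")
            labels.append(nd.taxon.label)
        for j, nd in enumerate(internal):
            index[nd] = len(leaves) + j
        n = len(leaves) + len(internal)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        for nd, i in index.items():
            if nd.parent_node is not None:
                parent[i] = index[nd.parent_node]
                if nd.edge.length is None:
                    who = nd.taxon.label if nd.taxon else "an internal node"
                    raise NewickError(f"missing branch length on the edge above {who}")
                lengths[i] = float(nd.edge.length)
        return cls(parent, lengths, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxon_namespace = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxon_namespace)
        nodes = [dendropy.Node() for _ in range(self.parent.size)]
        for i, lab in enumerate(self.tip_labels):
            nodes[i].taxon = taxon_namespace.new_taxon(lab)
        for i in range(self.parent.size):
            if i != self.root:
                nodes[self.parent[i]].add_child(nodes[i])
                nodes[i].edge.length = float(self.lengths[i])
        dtree.seed_node = nodes[self.root]
        return dtree

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        if "depths" not in self._cache:
            d = np.zeros(self.n_nodes)
            for node in self.postorder[::-1]:
                if node != self.root:
                    d[node] = d[self.parent[node]] + self.lengths[node]
            self._cache["depths"] = d
        return self._cache["depths"]

    def tip_depths(self) -> np.ndarray:
        return self.depths()[: self.n_tips]

    def height(self) -> float:
        return float(self.tip_depths().max())

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def ultrametric_deviation(self) -> float:
        """max over tips of |root-to-tip depth - mean depth|."""
        d = self.tip_depths()
        return float(np.max(np.abs(d - d.mean())))

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        return self.ultrametric_deviation() <= tol

    def scaled(self, height: float = 1.0) -> "PhyloTree":
        """Return a copy rescaled so the maximum root-to-tip depth equals *height*."""
        h = self.height()
        if h <= 0:
            raise ValueError("cannot rescale a zero-height tree")
        return PhyloTree(self.parent, self.lengths * (height / h), self.tip_labels)

    def tip_index(self, label: str) -> int:
        return self.tip_labels.index(normalize_name(label))

    # -- serialisation -------------------------------------------------

    def newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths required on all non-root edges)."""
    try:
        dtree = dendropy.Tree.get(
            file=io.StringIO(text),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"Newick parse error: {exc}") from exc
    return PhyloTree.from_dendropy(dtree)


def read_newick(path) -> PhyloTree:
    """Read a Newick tree from *path*; rejects malformed input and missing lengths."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    tree.write(path)


def collapse_zero_internal_branches(tree: PhyloTree, tol: float = 0.0) -> PhyloTree:
    """Collapse internal edges of length <= *tol* into polytomies.

    Zero-length terminal branches are always left alone; collapsing is only
    ever done on request because published chronograms legitimately contain
    hard polytomies encoded as zero-length edges.
    """
    parent = tree.parent.copy()
    keep = np.ones(tree.n_nodes, dtype=bool)
    for node in tree.postorder:
        if node == tree.root or node < tree.n_tips:
            continue
        if tree.lengths[node] <= tol:
            keep[node] = False
    # reattach children of collapsed nodes to their nearest kept ancestor
    for node in range(tree.n_nodes):
        p = parent[node]
        while p >= 0 and not keep[p]:
            p = parent[p]
        parent[node] = p
    old_ids = [i for i in range(tree.n_nodes) if keep[i]]
    remap = {o: i for i, o in enumerate(old_ids)}
    new_parent = np.array(
        [remap[parent[o]] if parent[o] >= 0 else -1 for o in old_ids], dtype=np.int64
    )
    new_lengths = np.array([tree.lengths[o] for o in old_ids])
    return PhyloTree(new_parent, new_lengths, tree.tip_labels)


def tipset_hashes(tree: PhyloTree) -> dict:
    """Short stable identifier per node: hash of its descendant tip-label set.

    Lets reconstructions from different runs (or prunings) be matched by
    clade content rather than by volatile node numbering.
    """
    import hashlib

    out = {}
    sets: dict[int, list] = {}
    for node in tree.postorder:
        if node < tree.n_tips:
            sets[node] = [tree.tip_labels[node]]
        else:
            merged: list = []
            for c in tree.children[node]:
                merged.extend(sets[c])
            sets[node] = merged
        out[node] = hashlib.sha256(
            ",".join(sorted(sets[node])).encode()
        ).hexdigest()[:12]
    return out


def vcv(tree: PhyloTree) -> PhyloCovariance:
    """Brownian-motion phylogenetic covariance matrix of a tree.

    ``C[i, j]`` is the depth (root-to-node path length) of the most recent
    common ancestor of tips *i* and *j*; the diagonal holds root-to-tip depths.
    """
    n = tree.n_tips
    depths = tree.depths()
    C = np.zeros((n, n))
    # tip sets per node, filled in postorder; cross-child tip pairs coalesce here
    tipsets: dict[int, np.ndarray] = {}
    for node in tree.postorder:
        if node < n:
            tipsets[node] = np.array([node], dtype=np.int64)
            C[node, node] = depths[node]
            continue
        groups = [tipsets.pop(c) for c in tree.children[node]]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                C[np.ix_(groups[a], groups[b])] = depths[node]
                C[np.ix_(groups[b], groups[a])] = depths[node]
        tipsets[node] = np.concatenate(groups)
    return PhyloCovariance(list(tree.tip_labels), C)


def prune_to_taxa(tree: PhyloTree, taxa) -> PhyloTree:
    """Restrict *tree* to the tips in *taxa*.

    Degree-2 internal nodes created by pruning are collapsed with branch
    lengths summed; root-to-tip depths of retained tips are unchanged (a
    degree-1 root is kept rather than collapsed, so depths are preserved).
    """
    wanted = [normalize_name(t) for t in taxa]
    unknown = sorted(set(wanted) - set(tree.tip_labels))
    if unknown:
        raise ValueError(f"taxa not in tree: {unknown}")
    keep_tip = np.zeros(tree.n_nodes, dtype=bool)
    for t in set(wanted):
        keep_tip[tree.tip_index(t)] = True
    # number of retained tips below each node
    n_below = np.zeros(tree.n_nodes, dtype=np.int64)
    for node in tree.postorder:
        if node < tree.n_tips:
            n_below[node] = int(keep_tip[node])
        else:
            n_below[node] = sum(n_below[c] for c in tree.children[node])
    if n_below[tree.root] == 0:
        raise ValueError("pruning would remove every tip")

    new_parent: list[int] = []
    new_lengths: list[float] = []
    new_labels: list[str] = []

    def emit_tip(old, length):
        new_parent.append(-2)  # placeholder, fixed below
        new_lengths.append(length)
        new_labels.append(tree.tip_labels[old])
        return len(new_parent) - 1

    records = []  # (new_index, parent_new_index)

    def build(old, extra, parent_slot):
        """Copy the retained part of the subtree at *old*; *extra* is length
        accumulated from collapsed ancestors."""
        length = float(tree.lengths[old]) + extra
        kids = [c for c in tree.children[old] if n_below[c] > 0]
        if old < tree.n_tips:
            idx = emit_tip(old, length)
            records.append((idx, parent_slot))
            return
        if len(kids) == 1 and old != tree.root:
            build(kids[0], length, parent_slot)
            return
        new_parent.append(-2)
        new_lengths.append(length)
        idx = len(new_parent) - 1
        records.append((idx, parent_slot))
        for c in kids:
            build(c, 0.0, idx)

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, tree.n_nodes * 2 + 100))
    try:
        build(tree.root, 0.0, -1)
    finally:
        sys.setrecursionlimit(old_limit)

    # renumber slots: tips first (in emission order), then internal nodes
    parents_set = {p for _, p in records if p >= 0}
    slots = list(range(len(new_parent)))
    tip_slots = [s for s in slots if s not in parents_set]
    internal_slots = [s for s in slots if s in parents_set]
    remap = {s: i for i, s in enumerate(tip_slots)}
    remap.update({s: len(tip_slots) + j for j, s in enumerate(internal_slots)})
    parent_arr = np.full(len(slots), -1, dtype=np.int64)
    length_arr = np.zeros(len(slots))
    for idx, parent_slot in records:
        length_arr[remap[idx]] = new_lengths[idx]
        parent_arr[remap[idx]] = remap[parent_slot] if parent_slot >= 0 else -1
    # emit_tip appended labels in the same order tip slots were created
    return PhyloTree(parent_arr, length_arr, new_labels)
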