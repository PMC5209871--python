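"""Phylogeny construction and likelihood under the WAG(+F) model.

Topology comes from neighbor joining on maximum-likelihood pairwise
distances; branch lengths are then fitted by coordinate-wise maximum
likelihood on the fixed topology (a user-supplied Newick topology is
accepted anywhere a tree is consumed). The likelihood is Felsenstein's
pruning algorithm with per-site rescaling; gap and ``X`` characters
contribute all-ones partial vectors (missing data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .io_core import (
    AA_INDEX,
    MISSING,
    MultipleAlignment,
    PhyloTree,
    TreeNode,
)
from .model import N_STATES, SubstitutionModel

logger = logging.getLogger(__name__)

MAX_DISTANCE = 20.0
_LOG_FLOOR = 1e-300


@dataclass
class DistanceMatrix:
    taxa: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        n = len(self.taxa)
        if D.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(D)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(D < -1e-12):
            raise ValueError("distances must be non-negative")
        self.D = D

    def get(self, a: str, b: str) -> float:
        return float(self.D[self.taxa.index(a), self.taxa.index(b)])


# ---------------------------------------------------------------------------
# pairwise ML distances
# ---------------------------------------------------------------------------

def ml_pairwise_distance(
    a: str, b: str, model: SubstitutionModel
) -> float:
    """ML distance (expected substitutions/site) for an aligned pair.

    Maximizes ``sum_sites log(pi_x P_xy(t))`` over ``t in [0, 20]`` by a
    coarse grid followed by bounded scalar refinement; columns with a
    gap or ``X`` in either sequence are skipped.
    """
    counts = np.zeros((N_STATES, N_STATES))
    for x, y in zip(a, b):
        if x in MISSING or y in MISSING:
            continue
        counts[AA_INDEX[x], AA_INDEX[y]] += 1
    if counts.sum() == 0:
        raise ValueError("no comparable columns between the two sequences")
    log_pi = np.log(model.pi)

    def neg_loglik(t: float) -> float:
        P = model.transition_matrix(t)
        logs = log_pi[:, None] + np.log(np.maximum(P, _LOG_FLOOR))
        return -float((counts * logs).sum())

    grid = np.concatenate(([0.0], np.geomspace(1e-5, MAX_DISTANCE, 120)))
    values = np.array([neg_loglik(t) for t in grid])
    best = int(np.argmin(values))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    t_hat, f_hat = grid[best], values[best]
    if hi > lo:
        res = minimize_scalar(
            neg_loglik, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if res.fun < f_hat:
            t_hat, f_hat = float(res.x), float(res.fun)
    return t_hat


def distance_matrix(
    msa: MultipleAlignment, model: SubstitutionModel
) -> DistanceMatrix:
    taxa = msa.ids
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_pairwise_distance(
                msa.records[i].sequence, msa.records[j].sequence, model
            )
    return DistanceMatrix(taxa, D)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei NJ with the Studier-Keppler criterion.

    Exact on additive matrices. Negative branch-length estimates are
    clamped to 0; ties in the join criterion break on the
    lexicographically smallest pair of cluster keys (a cluster's key is
    its smallest member taxon).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    # active clusters: key -> (TreeNode, index into d)
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in dm.taxa}
    d: dict[frozenset, float] = {}
    keys = list(dm.taxa)
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((keys[i], keys[j]))] = dm.D[i, j]

    while len(keys) > 3:
        r = len(keys)
        R = {k: sum(d[frozenset((k, m))] for m in keys if m != k) for k in keys}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = keys[i], keys[j]
                q = (r - 2) * d[frozenset((a, b))] - R[a] - R[b]
                pair = tuple(sorted((a, b)))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and pair < best[1]
                ):
                    best = (q, pair)
        a, b = best[1]
        dab = d[frozenset((a, b))]
        la = 0.5 * dab + (R[a] - R[b]) / (2 * (r - 2))
        lb = dab - la
        parent = TreeNode()
        na, nb = nodes.pop(a), nodes.pop(b)
        parent.add_child(na)
        parent.add_child(nb)
        na.length = max(la, 0.0)
        nb.length = max(lb, 0.0)
        new_key = min(a, b)
        for m in keys:
            if m in (a, b):
                continue
            dm_new = 0.5 * (
                d[frozenset((a, m))] + d[frozenset((b, m))] - dab
            )
            d[frozenset((new_key, m))] = max(dm_new, 0.0)
        keys = [m for m in keys if m not in (a, b)] + [new_key]
        keys.sort()
        nodes[new_key] = parent

    a, b, c = sorted(keys)
    dab = d[frozenset((a, b))]
    dac = d[frozenset((a, c))]
    dbc = d[frozenset((b, c))]
    root = TreeNode()
    for key, length in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        node = nodes.pop(key)
        root.add_child(node)
        node.length = max(length, 0.0)
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def leaf_partials(msa: MultipleAlignment) -> dict[str, np.ndarray]:
    """Per-leaf conditional likelihood arrays, (sites, 20); missing -> 1."""
    out = {}
    for rec in msa.records:
        arr = np.zeros((len(rec.sequence), N_STATES))
        for s, ch in enumerate(rec.sequence):
            if ch in MISSING:
                arr[s, :] = 1.0
            else:
                arr[s, AA_INDEX[ch]] = 1.0
        out[rec.id] = arr
    return out


def _pruning_pass(
    tree: PhyloTree,
    partials_by_leaf: dict[str, np.ndarray],
    model: SubstitutionModel,
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray], np.ndarray]:
    """Post-order partials (rescaled) per node, per-child up-lifted
    messages, and the accumulated per-site log scalers."""
    n_sites = next(iter(partials_by_leaf.values())).shape[0]
    partials: dict[int, np.ndarray] = {}
    messages: dict[int, np.ndarray] = {}  # id(child) -> P_child applied
    log_scale = np.zeros(n_sites)
    for node in tree.postorder():
        if node.is_leaf:
            if node.name not in partials_by_leaf:
                raise ValueError(f"leaf {node.name!r} missing from alignment")
            partials[id(node)] = partials_by_leaf[node.name]
        else:
            prod = np.ones((n_sites, N_STATES))
            for child in node.children:
                P = model.transition_matrix(child.length)
                msg = partials[id(child)] @ P.T
                messages[id(child)] = msg
                prod *= msg
            scale = prod.max(axis=1)
            safe = np.maximum(scale, _LOG_FLOOR)
            prod = prod / safe[:, None]
            log_scale += np.where(scale > 0, np.log(safe), -np.inf)
            partials[id(node)] = prod
    return partials, messages, log_scale


def site_log_likelihoods(
    tree: PhyloTree, msa: MultipleAlignment, model: SubstitutionModel
) -> np.ndarray:
    partials, _, log_scale = _pruning_pass(tree, leaf_partials(msa), model)
    root_lik = partials[id(tree.root)] @ model.pi
    return np.log(np.maximum(root_lik, _LOG_FLOOR)) + log_scale


def log_likelihood(
    tree: PhyloTree, msa: MultipleAlignment, model: SubstitutionModel
) -> float:
    """Total pruning log-likelihood of the alignment on the tree."""
    return float(site_log_likelihoods(tree, msa, model).sum())


def optimize_branch_lengths(
    tree: PhyloTree,
    msa: MultipleAlignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 50,
    max_length: float = MAX_DISTANCE,
) -> tuple[PhyloTree, float]:
    """Coordinate-wise ML branch lengths on a fixed topology.

    Sweeps over branches with bounded scalar optimization until the
    log-likelihood improves by less than ``tol``; the log-likelihood is
    non-decreasing across sweeps by construction.
    """
    t = tree.copy()
    pl = leaf_partials(msa)
    branches = [node for node in t.postorder() if node.parent is not None]

    def total() -> float:
        partials, _, log_scale = _pruning_pass(t, pl, model)
        root_lik = partials[id(t.root)] @ model.pi
        return float(
            (np.log(np.maximum(root_lik, _LOG_FLOOR)) + log_scale).sum()
        )

    current = total()
    for sweep in range(max_sweeps):
        previous = current
        for node in branches:
            old = node.length

            def neg(x: float) -> float:
                node.length = x
                return -total()

            res = minimize_scalar(
                neg, bounds=(0.0, max_length), method="bounded",
                options={"xatol": 1e-7},
            )
            if -res.fun > current:
                node.length = float(res.x)
                current = -res.fun
            else:
                node.length = old
        if current - previous < tol:
            break
    else:
        logger.warning(
            "branch-length optimization did not converge in %d sweeps",
            max_sweeps,
        )
    return t, current


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: PhyloTree, outgroup_id: str) -> PhyloTree:
    """Root on the midpoint of the outgroup's pendant edge."""
    t = tree.copy()
    leaf = t.find_leaf(outgroup_id)
    if leaf.parent is None:
        raise ValueError("cannot root a single-leaf tree")
    half = leaf.length / 2.0

    old_parent = leaf.parent
    old_parent.children.remove(leaf)
    leaf.parent = None

    chain: list[TreeNode] = []
    node = old_parent
    while node is not None:
        chain.append(node)
        node = node.parent
    edge_lengths = [nd.length for nd in chain]
    for i in range(len(chain) - 1):
        chain[i + 1].children.remove(chain[i])
    for nd in chain:
        nd.parent = None
    for i in range(len(chain) - 1):
        chain[i].add_child(chain[i + 1])
        chain[i + 1].length = edge_lengths[i]

    new_root = TreeNode()
    new_root.add_child(leaf)
    leaf.length = half
    new_root.add_child(old_parent)
    old_parent.length = half

    # suppress a unifurcation left at the old root
    for nd in chain:
        if not nd.is_leaf and len(nd.children) == 1 and nd.parent is not None:
            child = nd.children[0]
            child.length += nd.length
            grand = nd.parent
            idx = grand.children.index(nd)
            grand.children[idx] = child
            child.parent = grand
    if len(new_root.children) == 2 and any(
        not c.is_leaf and len(c.children) == 1 for c in new_root.children
    ):
        for c in list(new_root.children):
            if not c.is_leaf and len(c.children) == 1:
                child = c.children[0]
                child.length += c.length
                idx = new_root.children.index(c)
                new_root.children[idx] = child
                child.parent = new_root
    return PhyloTree(new_root, rooted=True)


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a bifurcating root into the trifurcating representation."""
    t = tree.copy()
    root = t.root
    if len(root.children) != 2:
        return t
    a, b = root.children
    if b.is_leaf and not a.is_leaf:
        a, b = b, a
    if b.is_leaf:
        raise ValueError("cannot unroot a two-leaf tree")
    # merge the root edge into b's children
    new_root = TreeNode()
    new_root.add_child(a)
    a.length = a.length + b.length
    for child in list(b.children):
        new_root.add_child(child)
    return PhyloTree(new_root, rooted=False)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def tree_bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial bipartitions, each canonicalized to one leaf side."""
    all_leaves = frozenset(tree.leaf_names())
    bips: set[frozenset] = set()
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        side = frozenset(
            leaf.name for leaf in node.postorder() if leaf.is_leaf
        )
        other = all_leaves - side
        if not other:
            continue
        bips.add(min(side, other, key=lambda s: sorted(s)))
    return bips


def bootstrap_support(
    msa: MultipleAlignment,
    model: SubstitutionModel,
    n_reps: int = 100,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Site-resampling bootstrap support for the NJ tree's bipartitions."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base_tree = neighbor_joining(distance_matrix(msa, model))
    targets = tree_bipartitions(base_tree)
    counts = {bip: 0 for bip in targets}
    rng = np.random.default_rng(seed)
    n_cols = msa.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = msa.subset_columns(list(cols))
        rep_tree = neighbor_joining(distance_matrix(rep, model))
        found = tree_bipartitions(rep_tree)
        for bip in targets:
            if bip in found:
                counts[bip] += 1
    return {bip: counts[bip] / n_reps for bip in targets}
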