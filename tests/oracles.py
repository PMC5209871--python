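"""Independent brute-force oracles used by the test suite.

Deliberately naive: exhaustive enumeration over internal-state
assignments (likelihood, marginal posteriors) and over the global
alignment lattice (affine-gap alignment score). They share no code with
the implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from lipevol.io_core import AA_INDEX, MISSING, MultipleAlignment, PhyloTree
from lipevol.model import N_STATES, SubstitutionModel


def _leaf_vector(ch: str) -> np.ndarray:
    v = np.zeros(N_STATES)
    if ch in MISSING:
        v[:] = 1.0
    else:
        v[AA_INDEX[ch]] = 1.0
    return v


def enumerate_site_likelihood_and_posteriors(
    tree: PhyloTree,
    msa: MultipleAlignment,
    model: SubstitutionModel,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Per-site likelihoods and per-internal-node marginal posteriors by
    summation over every internal-state assignment."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = {n.name: n for n in tree.leaves()}
    edges = [n for n in tree.postorder() if n.parent is not None]
    P_of = {id(n): model.transition_matrix(n.length) for n in edges}
    n_sites = msa.n_columns

    site_liks = np.zeros(n_sites)
    post = {n.label: np.zeros((n_sites, N_STATES)) for n in internals}
    for s in range(n_sites):
        leaf_vecs = {
            id(leaves[r.id]): _leaf_vector(r.sequence[s])
            for r in msa.records
        }
        for assign in itertools.product(range(N_STATES), repeat=len(internals)):
            state = {id(n): a for n, a in zip(internals, assign)}
            p = model.pi[state[id(tree.root)]]
            for n in edges:
                parent_state = state[id(n.parent)]
                if n.is_leaf:
                    p *= float(P_of[id(n)][parent_state] @ leaf_vecs[id(n)])
                else:
                    p *= P_of[id(n)][parent_state, state[id(n)]]
                if p == 0.0:
                    break
            site_liks[s] += p
            for n, a in zip(internals, assign):
                post[n.label][s, a] += p
    for label in post:
        post[label] /= post[label].sum(axis=1, keepdims=True)
    return site_liks, post


def enumerate_global_alignments(a: str, b: str):
    """All global alignments of a and b as (gapped_a, gapped_b) pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in enumerate_global_alignments(a[:-1], b):
            yield ga + a[-1], gb + "-"
    if b:
        for ga, gb in enumerate_global_alignments(a, b[:-1]):
            yield ga + "-", gb + b[-1]
    if a and b:
        for ga, gb in enumerate_global_alignments(a[:-1], b[:-1]):
            yield ga + a[-1], gb + b[-1]


def affine_alignment_score(
    gapped_a: str,
    gapped_b: str,
    score_fn,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Score a gapped pair: a gap run of length k costs open + ext*(k-1)."""
    total = 0.0
    prev = None  # "A" gap in a, "B" gap in b, "M" aligned pair
    for x, y in zip(gapped_a, gapped_b):
        if x == "-":
            total -= gap_open if prev != "A" else gap_extend
            prev = "A"
        elif y == "-":
            total -= gap_open if prev != "B" else gap_extend
            prev = "B"
        else:
            total += score_fn(x, y)
            prev = "M"
    return total


def best_alignment_score(
    a: str, b: str, score_fn, gap_open: float, gap_extend: float
) -> float:
    return max(
        affine_alignment_score(ga, gb, score_fn, gap_open, gap_extend)
        for ga, gb in enumerate_global_alignments(a, b)
    )
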