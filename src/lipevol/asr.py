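"""Marginal ancestral sequence reconstruction.

For every internal node ``v`` and alignment column ``s`` the posterior
probability of ancestral state ``a`` is

    p_vs(a)  ∝  O_v(a) · D_v(a)

where ``D_v`` is the ordinary pruning partial (likelihood of the data in
the subtree below ``v`` given state ``a``) and ``O_v`` the joint
likelihood of the data outside the subtree together with the prior:
``O_root(a) = pi_a`` and, for a child ``c`` of ``v`` with branch length
``t_c`` and siblings ``s``,

    O_c(b) = sum_a O_v(a) · prod_{s != c} M_s(a) · P_ab(t_c),

with ``M_s(a) = sum_b P_ab(t_s) D_s(b)`` the up-lifted child message.
This up-down pass is the reversible-model equivalent of re-rooting at
each node. Gaps and ``X`` are missing data, so states are reconstructed
at every alignment column — columns gapped in many extant sequences
simply come out with diffuse, low-confidence posteriors (which is
exactly what posterior-threshold trimming of the lid consumes).

The MAP sequence takes the argmax residue per column; ties break on the
lowest alphabet index (A R N D C Q E G H I L K M F P S T W Y V), which
makes reconstructions deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ALPHABET, MultipleAlignment, PhyloTree, ProteinRecord
from .model import N_STATES, SubstitutionModel
from .phylo import _pruning_pass, leaf_partials

_FLOOR = 1e-300


@dataclass
class PosteriorMatrix:
    """Sites x 20 marginal posterior probabilities at one internal node."""

    node_id: int
    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[1] != N_STATES:
            raise ValueError("posterior matrix must be sites x 20")
        self.P = P

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.P, columns=list(ALPHABET))
        df.insert(0, "site", np.arange(1, len(df) + 1))  # 1-based report
        df["map_residue"] = [ALPHABET[i] for i in self.P.argmax(axis=1)]
        df["max_posterior"] = self.P.max(axis=1)
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(
            path, sep="\t", index=False, float_format="%.6f"
        )


@dataclass
class AncestralReconstruction:
    """MAP sequence and per-site confidence at one internal node."""

    node_id: int
    map_sequence: str
    max_posterior: np.ndarray

    def __post_init__(self) -> None:
        if len(self.map_sequence) != len(self.max_posterior):
            raise ValueError("sequence/posterior length mismatch")


def _posterior_pass(
    tree: PhyloTree, msa: MultipleAlignment, model: SubstitutionModel
) -> dict[int, np.ndarray]:
    """Marginal posteriors for every internal node (keyed by node label)."""
    pl = leaf_partials(msa)
    partials, messages, _ = _pruning_pass(tree, pl, model)
    n_sites = msa.n_columns

    outside: dict[int, np.ndarray] = {
        id(tree.root): np.tile(model.pi, (n_sites, 1))
    }
    posteriors: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        O = outside[id(node)]
        joint = O * partials[id(node)]
        norm = joint.sum(axis=1, keepdims=True)
        posteriors[node.label] = joint / np.maximum(norm, _FLOOR)
        for child in node.children:
            if child.is_leaf:
                continue
            sib_prod = O.copy()
            for sib in node.children:
                if sib is not child:
                    sib_prod *= messages[id(sib)]
            P = model.transition_matrix(child.length)
            O_child = sib_prod @ P
            # rescale per site; constants cancel in the normalization
            scale = O_child.max(axis=1, keepdims=True)
            outside[id(child)] = O_child / np.maximum(scale, _FLOOR)
    return posteriors


def marginal_posteriors(
    tree: PhyloTree,
    msa: MultipleAlignment,
    model: SubstitutionModel,
    node_id: int,
) -> PosteriorMatrix:
    """Posterior state distribution at one internal node (by label)."""
    node = tree.node_by_label(node_id)
    if node.is_leaf:
        raise ValueError(f"node {node_id} is a leaf; posteriors are "
                         "defined for internal nodes only")
    posteriors = _posterior_pass(tree, msa, model)
    return PosteriorMatrix(node_id, posteriors[node_id])


def reconstruct_all(
    tree: PhyloTree, msa: MultipleAlignment, model: SubstitutionModel
) -> tuple[dict[int, AncestralReconstruction], dict[int, PosteriorMatrix]]:
    """MAP reconstruction and posterior matrix for every internal node.

    Reconstructions cover every alignment column, including columns that
    are gapped in most extant sequences.
    """
    raw = _posterior_pass(tree, msa, model)
    recs: dict[int, AncestralReconstruction] = {}
    mats: dict[int, PosteriorMatrix] = {}
    for label, P in raw.items():
        idx = P.argmax(axis=1)  # first max = lowest alphabet index
        recs[label] = AncestralReconstruction(
            node_id=label,
            map_sequence="".join(ALPHABET[i] for i in idx),
            max_posterior=P.max(axis=1),
        )
        mats[label] = PosteriorMatrix(label, P)
    return recs, mats


def map_records(
    reconstructions: dict[int, AncestralReconstruction]
) -> list[ProteinRecord]:
    """MAP sequences as FASTA-ready records, ids ``node_<label>``."""
    return [
        ProteinRecord(f"node_{label}", rec.map_sequence)
        for label, rec in sorted(reconstructions.items())
    ]
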