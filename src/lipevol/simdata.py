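"""Synthetic protein families with known trees, ancestors and lid dynamics.

The generator emulates the structure of a fungal versatile-lipase family:
sequences evolve on a (Yule or user-supplied) tree under the WAG model,
with

* an N-terminal signal-peptide block (Met followed by strongly
  hydrophobic residues) evolving slowly,
* near-conserved oxyanion-hole (``GGGF``) and catalytic-serine
  (``GESAG``) motif blocks,
* a contiguous "lid" segment evolving at an elevated substitution rate
  and accumulating deletions, so extant lid lengths vary while every
  ancestor remains defined at all lid columns.

Indels are modelled as deletions only (geometric run lengths, lid
columns only); the root therefore defines the alignment's column space
and the simulation-known homology is exact. Every output is a pure
function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import screen as _screen
from .align import AlignParams, global_align, percent_identity
from .io_core import (
    ALPHABET,
    GAP,
    MultipleAlignment,
    PhyloTree,
    ProteinRecord,
    TreeNode,
)
from .model import SubstitutionModel, build_wag_model

_GAP_STATE = -1
#: Residues used for the hydrophobic core of simulated signal peptides
#: (all with Kyte-Doolittle hydropathy >= 2.8).
_SIGNAL_RESIDUES = "LIVF"


@dataclass
class SimulationConfig:
    """Parameters of the family simulator.

    Intervals are 0-based half-open on the root sequence. The defaults
    describe a desk-scale family: 8 taxa, 300 columns, a 52-column lid
    (matching the full-length ancestral lid block of the real protein
    family), lid substitution rate x3 and a 5% per-branch per-position
    lid deletion probability with geometric mean run length 2.
    """

    n_leaves: int = 8
    tree_mode: str = "yule"  # "yule" | "fixed_newick"
    newick: str | None = None
    mean_branch_length: float = 0.1
    root_length: int = 300
    lid_interval: tuple[int, int] = (180, 232)
    lid_rate_multiplier: float = 3.0
    lid_indel_prob: float = 0.05
    indel_mean_length: float = 2.0
    signal_length: int = 18
    oxyanion_position: int = 60
    catalytic_position: int = 120
    conserved_rate_multiplier: float = 0.1
    frequency_mode: str = "wag_default"
    seed: int = 0

    def __post_init__(self) -> None:
        s, e = self.lid_interval
        if not (0 <= s < e <= self.root_length):
            raise ValueError("lid interval outside root sequence")
        for name, pos, width in [
            ("oxyanion", self.oxyanion_position, 4),
            ("catalytic", self.catalytic_position, 5),
        ]:
            if not (0 <= pos and pos + width <= self.root_length):
                raise ValueError(f"{name} motif outside root sequence")
            if pos + width > s and pos < e:
                raise ValueError(f"{name} motif overlaps the lid interval")
        if self.signal_length > s or self.signal_length >= self.root_length:
            raise ValueError("signal block must precede the lid")
        for rate in (
            self.lid_rate_multiplier,
            self.lid_indel_prob,
            self.conserved_rate_multiplier,
            self.mean_branch_length,
        ):
            if rate < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class SyntheticFamily:
    """A simulated family with full ground truth."""

    true_tree: PhyloTree
    #: internal node label -> ungapped ancestral sequence
    true_ancestors: dict[int, str]
    #: internal node label -> gapped ancestral row (alignment columns)
    aligned_ancestors: dict[int, str]
    extant: list[ProteinRecord]
    true_alignment: MultipleAlignment
    true_lid_columns: list[int]
    config: SimulationConfig
    seed: int

    @property
    def root_label(self) -> int:
        return self.true_tree.root.label

    def extant_lid_lengths(self) -> dict[str, int]:
        """Surviving lid residues per extant record."""
        out = {}
        for rec in self.true_alignment.records:
            out[rec.id] = sum(
                1 for j in self.true_lid_columns if rec.sequence[j] != GAP
            )
        return out


def simulate_tree(
    n_leaves: int,
    mode: str = "yule",
    mean_branch_length: float = 0.1,
    newick: str | None = None,
    seed: int = 0,
) -> PhyloTree:
    """Rooted binary tree: Yule topology, Exp(mean) branch lengths."""
    if mode == "fixed_newick":
        from .io_core import parse_newick

        if newick is None:
            raise ValueError("fixed_newick mode requires a newick string")
        return parse_newick(newick)
    if mode != "yule":
        raise ValueError(f"unknown tree mode {mode!r}")
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    leaves = [root.add_child(TreeNode()), root.add_child(TreeNode())]
    while len(leaves) < n_leaves:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        leaves.append(node.add_child(TreeNode()))
        leaves.append(node.add_child(TreeNode()))
    # name leaves in discovery (preorder) order for determinism
    counter = 0
    for node in root.preorder():
        if node.is_leaf:
            counter += 1
            node.name = f"t{counter:02d}"
    for node in root.postorder():
        if node.parent is not None:
            node.length = float(rng.exponential(mean_branch_length))
    return PhyloTree(root, rooted=True)


def _draw_root_sequence(
    config: SimulationConfig, model: SubstitutionModel, rng: np.random.Generator
) -> np.ndarray:
    states = rng.choice(20, size=config.root_length, p=model.pi)
    aa = {a: i for i, a in enumerate(ALPHABET)}
    sig = [aa["M"]] + [
        aa[_SIGNAL_RESIDUES[int(rng.integers(len(_SIGNAL_RESIDUES)))]]
        for _ in range(config.signal_length - 1)
    ]
    states[: config.signal_length] = sig
    for pos, motif in [
        (config.oxyanion_position, "GGGF"),
        (config.catalytic_position, "GESAG"),
    ]:
        states[pos : pos + len(motif)] = [aa[c] for c in motif]
    return states


def _rate_classes(config: SimulationConfig) -> np.ndarray:
    rates = np.ones(config.root_length)
    rates[: config.signal_length] = config.conserved_rate_multiplier
    rates[0] = 0.0  # initiator methionine is invariant
    for pos, width in [
        (config.oxyanion_position, 4),
        (config.catalytic_position, 5),
    ]:
        rates[pos : pos + width] = config.conserved_rate_multiplier
    s, e = config.lid_interval
    rates[s:e] = config.lid_rate_multiplier
    return rates


def _evolve_branch(
    parent_states: np.ndarray,
    t: float,
    rates: np.ndarray,
    config: SimulationConfig,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> np.ndarray:
    child = parent_states.copy()
    present = child != _GAP_STATE
    for rate in np.unique(rates):
        P = model.transition_matrix(rate * t)
        idx = np.flatnonzero(present & (rates == rate))
        if idx.size == 0:
            continue
        cum = np.cumsum(P[child[idx]], axis=1)
        u = rng.random(idx.size)
        child[idx] = np.minimum((cum < u[:, None]).sum(axis=1), 19)
    # deletions restricted to the lid block
    s, e = config.lid_interval
    if config.lid_indel_prob > 0:
        lid_present = [j for j in range(s, e) if child[j] != _GAP_STATE]
        k = 0
        while k < len(lid_present):
            if rng.random() < config.lid_indel_prob:
                run = int(rng.geometric(1.0 / config.indel_mean_length))
                for j in lid_present[k : k + run]:
                    child[j] = _GAP_STATE
                k += run
            else:
                k += 1
    return child


def _states_to_row(states: np.ndarray) -> str:
    return "".join(
        GAP if s == _GAP_STATE else ALPHABET[s] for s in states
    )


def simulate_family(config: SimulationConfig) -> SyntheticFamily:
    """Simulate one family; see the module docstring for the model."""
    rng = np.random.default_rng(config.seed)
    model = build_wag_model("wag_default")
    tree = simulate_tree(
        config.n_leaves,
        config.tree_mode,
        config.mean_branch_length,
        config.newick,
        seed=int(rng.integers(2**31)),
    )
    rates = _rate_classes(config)
    root_states = _draw_root_sequence(config, model, rng)

    states_of: dict[int, np.ndarray] = {id(tree.root): root_states}
    for node in tree.preorder():
        if node.parent is None:
            continue
        states_of[id(node)] = _evolve_branch(
            states_of[id(node.parent)], node.length, rates, config, model, rng
        )

    aligned_ancestors = {
        node.label: _states_to_row(states_of[id(node)])
        for node in tree.internal_nodes()
    }
    true_ancestors = {
        lab: row.replace(GAP, "") for lab, row in aligned_ancestors.items()
    }

    s, e = config.lid_interval
    extant: list[ProteinRecord] = []
    rows: list[ProteinRecord] = []
    for leaf in tree.leaves():
        row = _states_to_row(states_of[id(leaf)])
        rows.append(ProteinRecord(leaf.name, row))
        ungapped = row.replace(GAP, "")
        n_lid = sum(1 for j in range(s, e) if row[j] != GAP)
        features = {"signal": (0, config.signal_length)}
        if n_lid:
            features["lid"] = (s, s + n_lid)  # deletions occur only in lid
        extant.append(ProteinRecord(leaf.name, ungapped, features))

    return SyntheticFamily(
        true_tree=tree,
        true_ancestors=true_ancestors,
        aligned_ancestors=aligned_ancestors,
        extant=extant,
        true_alignment=MultipleAlignment(rows),
        true_lid_columns=list(range(s, e)),
        config=config,
        seed=config.seed,
    )


def write_family(family: SyntheticFamily, out_dir) -> None:
    """Write a self-describing fixture directory for a simulated family.

    Emits extant FASTA, true-alignment FASTA, true-tree Newick (with
    internal node labels), ancestors FASTA (ungapped MAP-comparable
    truth) and the config as JSON.
    """
    import dataclasses
    import json
    from pathlib import Path

    from .io_core import write_alignment, write_fasta, write_newick

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(family.extant, out / "extant.fasta")
    write_alignment(family.true_alignment, out / "true_alignment.fasta")
    write_newick(family.true_tree, out / "true_tree.nwk", internal_labels=True)
    write_fasta(
        [
            ProteinRecord(f"node_{label}", seq)
            for label, seq in sorted(family.true_ancestors.items())
        ],
        out / "true_ancestors.fasta",
    )
    meta = dataclasses.asdict(family.config)
    meta["true_lid_columns_1based"] = [
        family.true_lid_columns[0] + 1,
        family.true_lid_columns[-1] + 1,
    ]
    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# screening fixture
# ---------------------------------------------------------------------------

@dataclass
class ScreeningFixture:
    """Planted positives, decoys and the reference they are screened against."""

    records: list[ProteinRecord]
    labels: dict[str, bool]
    reference: ProteinRecord
    seed: int


def _shuffle_decoy(
    source: ProteinRecord,
    name: str,
    reference: ProteinRecord,
    params: AlignParams,
    rng: np.random.Generator,
    max_tries: int = 50,
) -> ProteinRecord:
    """Composition-matched shuffle verified to be motif-free, signal-free
    and below the identity threshold."""
    chars = np.array(list(source.sequence))
    for _ in range(max_tries):
        shuffled = "".join(rng.permutation(chars))
        rec = ProteinRecord(name, shuffled)
        hits = _screen.find_motifs(rec)
        if hits.oxyanion or hits.catalytic:
            continue
        if _screen.predict_signal_peptide(rec).present:
            continue
        ident = percent_identity(global_align(rec, reference, params))
        if ident >= 0.30:
            continue
        return rec
    raise RuntimeError(f"could not build a valid decoy from {source.id}")


def make_screening_fixture(
    n_true: int,
    n_decoys: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> ScreeningFixture:
    """Planted true-like lipases plus composition-matched shuffle decoys.

    Positives are extant members of a simulated family (signal block,
    both motifs, lid >= 20 residues, >= 30% identity to the emitted
    reference, which is the family's root sequence). Decoys are shuffles
    of the positives verified to carry none of those signals. The
    construction is validated and re-drawn (bounded, seed-derived) until
    the guarantees hold, so downstream recovery tests are exact.
    """
    if config is None:
        config = SimulationConfig(
            n_leaves=max(n_true, 3),
            mean_branch_length=0.05,
            lid_indel_prob=0.02,
        )
    params = AlignParams()
    for attempt in range(20):
        fam_seed = (seed * 1000 + attempt) % (2**31)
        fam = simulate_family(replace(config, seed=fam_seed))
        reference = ProteinRecord(
            "reference",
            fam.true_ancestors[fam.root_label],
            {
                "signal": (0, config.signal_length),
                "lid": tuple(config.lid_interval),
            },
        )
        positives = fam.extant[:n_true]
        if len(positives) < n_true:
            raise ValueError("n_true exceeds the number of simulated leaves")
        ok = True
        for rec in positives:
            hits = _screen.find_motifs(rec)
            if not (hits.oxyanion and hits.catalytic):
                ok = False
                break
            if not _screen.predict_signal_peptide(rec).present:
                ok = False
                break
            lid = _screen.extract_lid(rec, reference, params)
            if lid.length < 20:
                ok = False
                break
            if percent_identity(global_align(rec, reference, params)) < 0.30:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("failed to simulate a fully valid positive set")

    rng = np.random.default_rng(seed + 7919)
    positives = [
        ProteinRecord(f"pos_{i + 1:02d}", rec.sequence, dict(rec.features))
        for i, rec in enumerate(positives)
    ]
    decoys = [
        _shuffle_decoy(
            positives[i % len(positives)] if positives else reference,
            f"decoy_{i + 1:02d}",
            reference,
            params,
            rng,
        )
        for i in range(n_decoys)
    ]
    records = positives + decoys
    labels = {rec.id: rec.id.startswith("pos_") for rec in records}
    return ScreeningFixture(records, labels, reference, seed)
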