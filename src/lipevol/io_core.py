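"""Shared sequence, alignment and tree types plus FASTA/Newick I/O.

Conventions used throughout the package:

* Amino-acid alphabet order is the conventional order of the WAG
  publication, ``A R N D C Q E G H I L K M F P S T W Y V``; every
  20-vector and 20x20 matrix in the package uses this order.
* Intervals are 0-based half-open internally and 1-based inclusive in
  every user-facing report.
* ``X`` (unknown residue) and ``-`` (alignment gap) are both treated as
  missing data by the likelihood machinery.
* Internal tree nodes are numbered in PAML's style: leaves ``1..N`` in
  input order, internal nodes from ``N+1`` upward in post-order, so that
  node labels are comparable to published "node 128"-style labels.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical residue order (WAG publication order).
ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
GAP = "-"
UNKNOWN = "X"
#: Characters treated as missing data in likelihood computations.
MISSING = {GAP, UNKNOWN}

_VALID_CHARS = set(ALPHABET) | MISSING


class FormatError(ValueError):
    """Raised for malformed FASTA/Newick input."""


@dataclass
class ProteinRecord:
    """A named amino-acid sequence with optional feature intervals.

    Parameters
    ----------
    id:
        Non-empty identifier, unique within any collection.
    sequence:
        Residues over the 20 canonical letters plus ``X``; ``-`` is
        permitted only in alignment context.
    features:
        Mapping of feature name to a 0-based half-open ``(start, end)``
        interval on the sequence (e.g. ``{"lid": (305, 357)}``).
    """

    id: str
    sequence: str
    features: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("record id must be non-empty")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )
        for name, (start, end) in self.features.items():
            if not (0 <= start < end <= len(self.sequence)):
                raise FormatError(
                    f"record {self.id!r}: feature {name!r} interval "
                    f"({start}, {end}) outside sequence of length "
                    f"{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ungapped(self) -> str:
        """Sequence with gap characters removed."""
        return self.sequence.replace(GAP, "")

    def feature_interval_report(self, name: str) -> tuple[int, int]:
        """Feature interval in 1-based inclusive coordinates."""
        start, end = self.features[name]
        return start + 1, end


@dataclass
class MultipleAlignment:
    """Equal-length gapped sequences with a shared column index."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment must contain at least one record")
        n = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != n:
                raise FormatError(
                    f"record {rec.id!r} has length {len(rec.sequence)}, "
                    f"expected {n}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rec_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    def column(self, j: int) -> str:
        return "".join(r.sequence[j] for r in self.records)

    def subset_columns(self, columns: Sequence[int]) -> "MultipleAlignment":
        """New alignment restricted to the given column indices (in order)."""
        recs = [
            ProteinRecord(r.id, "".join(r.sequence[j] for j in columns))
            for r in self.records
        ]
        return MultipleAlignment(recs)


class TreeNode:
    """Node of a :class:`PhyloTree` (leaf iff no children)."""

    __slots__ = ("name", "label", "length", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float = 0.0,
        label: int | None = None,
    ) -> None:
        self.name = name
        self.label = label
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = self.name if self.name is not None else f"#{self.label}"
        return f"<TreeNode {tag} len={self.length:g}>"


class PhyloTree:
    """Rooted or unrooted phylogeny with branch lengths.

    An unrooted tree is represented with a trifurcating root. Leaf names
    are unique; node labels follow the PAML numbering convention (see
    module docstring) and are recomputed by :meth:`assign_labels`
    whenever the topology changes.
    """

    def __init__(self, root: TreeNode, rooted: bool = True) -> None:
        self.root = root
        self.rooted = rooted
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None for n in names):
            raise FormatError("every leaf must carry a name")
        if len(set(names)) != len(names):
            raise FormatError("leaf names must be unique")
        self.assign_labels()

    # -- traversal ---------------------------------------------------------

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if not n.is_leaf]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def find_leaf(self, name: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"no leaf named {name!r}")

    def node_by_label(self, label: int) -> TreeNode:
        for node in self.root.postorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label}")

    # -- labelling ---------------------------------------------------------

    def assign_labels(self) -> None:
        """Leaves ``1..N`` in input (preorder) order, internals ``N+1..``
        in post-order — PAML's numbering convention."""
        leaves_in_order = [n for n in self.root.preorder() if n.is_leaf]
        for i, leaf in enumerate(leaves_in_order, start=1):
            leaf.label = i
        next_label = len(leaves_in_order) + 1
        for node in self.root.postorder():
            if not node.is_leaf:
                node.label = next_label
                next_label += 1

    # -- copying / export --------------------------------------------------

    def copy(self) -> "PhyloTree":
        def _copy(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length, node.label)
            for child in node.children:
                new.add_child(_copy(child))
            return new

        return PhyloTree(_copy(self.root), rooted=self.rooted)

    def newick(self, internal_labels: bool = False) -> str:
        """Newick string; branch lengths to 12 significant digits."""

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                lab = ""
                if internal_labels and node.label is not None:
                    lab = str(node.label)
                core = f"({inner}){lab}"
            if node.parent is None:
                return core
            return f"{core}:{node.length:.12g}"

        return fmt(self.root) + ";"

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.root.postorder() if n.parent)

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between all leaf pairs (keys sorted name pairs)."""
        dists: dict[tuple[str, str], float] = {}
        # distance from every node down to each descendant leaf
        below: dict[int, dict[str, float]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[id(node)] = {node.name: 0.0}
            else:
                merged: dict[str, float] = {}
                child_maps = []
                for child in node.children:
                    cmap = {
                        k: v + child.length
                        for k, v in below[id(child)].items()
                    }
                    child_maps.append(cmap)
                    merged.update(cmap)
                below[id(node)] = merged
                for i in range(len(child_maps)):
                    for j in range(i + 1, len(child_maps)):
                        for a, da in child_maps[i].items():
                            for b, db in child_maps[j].items():
                                key = (a, b) if a < b else (b, a)
                                dists[key] = da + db
        return dists


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased; letters outside the canonical alphabet
    (e.g. ``B``, ``Z``, ``*``) are mapped to ``X`` with a logged warning.
    Raises :class:`FormatError` for an empty file, duplicate ids or a
    zero-length sequence, naming the offending record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        if not seq:
            raise FormatError(f"record {rec.id!r} in {path}: empty sequence")
        bad = set(seq) - _VALID_CHARS
        if bad:
            logger.warning(
                "record %r: mapping unknown letters %s to 'X'",
                rec.id, sorted(bad),
            )
            seq = re.sub(f"[^{ALPHABET}{GAP}{UNKNOWN}]", UNKNOWN, seq)
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path, line_width: int = 60) -> None:
    """Write records as FASTA, preserving order; UTF-8, LF endings."""
    if not records:
        logger.warning("writing empty FASTA file %s", path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i:i + line_width] + "\n")


def read_alignment(path) -> MultipleAlignment:
    """Read an aligned FASTA file."""
    return MultipleAlignment(read_fasta(path))


def write_alignment(msa: MultipleAlignment, path, line_width: int = 60) -> None:
    write_fasta(msa.records, path, line_width=line_width)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: "dendropy.Tree") -> PhyloTree:
    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise FormatError("leaf without a name in Newick input")
            node = TreeNode(name=dnode.taxon.label)
        else:
            node = TreeNode()
        length = dnode.edge.length
        if length is not None:
            if length < 0:
                where = (
                    dnode.taxon.label if dnode.taxon else "an internal node"
                )
                raise FormatError(
                    f"negative branch length {length} on edge above {where}"
                )
            node.length = float(length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    rooted = len(root.children) == 2
    tree = PhyloTree(root, rooted=rooted)
    # preserve integer internal labels from the file if present
    labels = {}
    for dnode, node in zip(dtree.seed_node.preorder_iter(), root.preorder()):
        if not dnode.is_leaf() and dnode.label:
            try:
                labels[id(node)] = int(dnode.label)
            except ValueError:
                pass
    if labels:
        for node in root.preorder():
            if id(node) in labels:
                node.label = labels[id(node)]
    return tree


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise FormatError(f"Newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick(path) -> PhyloTree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree, path, internal_labels: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(tree.newick(internal_labels=internal_labels) + "\n")
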