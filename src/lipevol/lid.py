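"""Lid-region analysis: trimming, hydrophobicity and trajectories.

The lid of a versatile lipase is a mobile amphipathic helix covering the
catalytic pocket; its length and hydrophobicity modulate substrate
specificity. Because gaps are treated as missing data, ancestral
reconstructions span the full lid column block regardless of how many
extant sequences carry residues there — the length of an ancestral lid
is therefore *estimated* by deleting low-confidence residues: a residue
is kept iff its maximum posterior probability is >= the threshold
(strictly-below deleted; ties at the threshold kept). Six thresholds
(0.65-0.90) are swept by default.

Hydrophobic percentages are truncated (floored) to one decimal by
default — e.g. 5/12 -> 41.6 and 22/35 -> 62.8; rounding is available as
an option. The default hydrophobic set is the residues with positive
Kyte-Doolittle hydropathy: ``{I, V, L, F, C, M, A}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asr import AncestralReconstruction, PosteriorMatrix
from .io_core import GAP, MultipleAlignment, ProteinRecord
from .screen import CATALYTIC_PATTERN, OXYANION_PATTERN, find_motifs

#: Kyte-Doolittle hydropathy > 0.
DEFAULT_HYDROPHOBIC = frozenset("IVLFCMA")
#: Default posterior thresholds for the trimming sweep.
DEFAULT_THRESHOLDS = (0.65, 0.70, 0.75, 0.80, 0.85, 0.90)


@dataclass
class LidRegion:
    """Lid residues of one extant record or ancestral reconstruction."""

    node_or_record_id: str | int
    residues: str
    source_columns: list[int]
    per_residue_posterior: np.ndarray  # all 1.0 for extant sequences

    def __post_init__(self) -> None:
        self.per_residue_posterior = np.asarray(
            self.per_residue_posterior, dtype=float
        )
        if not (
            len(self.residues)
            == len(self.source_columns)
            == len(self.per_residue_posterior)
        ):
            raise ValueError("residues/columns/posteriors length mismatch")

    def __len__(self) -> int:
        return len(self.residues)


def lid_columns(
    msa: MultipleAlignment,
    reference_id: str,
    lid_interval: tuple[int, int] | None = None,
) -> list[int]:
    """Alignment columns spanned by the reference's lid residues.

    ``lid_interval`` is 0-based half-open on the reference's ungapped
    sequence; if omitted it is taken from the reference record's
    ``lid`` feature. The returned block is contiguous and includes any
    insertion columns between the first and last lid residue.
    """
    try:
        ref = msa[reference_id]
    except KeyError:
        raise ValueError(f"reference {reference_id!r} absent from alignment")
    if lid_interval is None:
        if "lid" not in ref.features:
            raise ValueError("reference carries no lid feature")
        lid_interval = ref.features["lid"]
    start, end = lid_interval
    cols = []
    ri = 0
    for j, ch in enumerate(ref.sequence):
        if ch != GAP:
            if start <= ri < end:
                cols.append(j)
            ri += 1
    if not cols:
        raise ValueError("reference lid interval maps to no columns")
    return list(range(cols[0], cols[-1] + 1))


def ancestral_lid(
    reconstruction: AncestralReconstruction,
    columns: list[int],
) -> LidRegion:
    """Full-length lid of an ancestral MAP sequence with confidences."""
    return LidRegion(
        node_or_record_id=reconstruction.node_id,
        residues="".join(reconstruction.map_sequence[j] for j in columns),
        source_columns=list(columns),
        per_residue_posterior=reconstruction.max_posterior[list(columns)],
    )


def extant_lid(record: ProteinRecord, columns: list[int]) -> LidRegion:
    """Observed lid residues of an aligned extant record (gaps dropped)."""
    kept = [j for j in columns if record.sequence[j] != GAP]
    return LidRegion(
        node_or_record_id=record.id,
        residues="".join(record.sequence[j] for j in kept),
        source_columns=kept,
        per_residue_posterior=np.ones(len(kept)),
    )


def trim_by_posterior(lid: LidRegion, threshold: float) -> LidRegion:
    """Keep exactly the residues with max posterior >= threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    keep = [
        i for i, p in enumerate(lid.per_residue_posterior) if p >= threshold
    ]
    return LidRegion(
        node_or_record_id=lid.node_or_record_id,
        residues="".join(lid.residues[i] for i in keep),
        source_columns=[lid.source_columns[i] for i in keep],
        per_residue_posterior=lid.per_residue_posterior[keep],
    )


def hydrophobic_fraction(
    residues: str,
    hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC,
    mode: str = "truncate",
) -> tuple[int, float]:
    """Hydrophobic residue count and one-decimal percentage.

    The percentage is truncated to one decimal by default (integer
    arithmetic, so 5/12 gives exactly 41.6); ``mode="round"`` rounds
    instead.
    """
    if not residues:
        raise ValueError("empty residue string")
    count = sum(1 for c in residues if c in hydrophobic_set)
    if mode == "truncate":
        percent = (1000 * count // len(residues)) / 10.0
    elif mode == "round":
        percent = round(100.0 * count / len(residues), 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return count, percent


def lid_trajectory(
    reconstructions: dict[int, AncestralReconstruction],
    columns: list[int],
    node_ids: list[int] | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC,
    oxyanion_pattern: str = OXYANION_PATTERN,
    catalytic_pattern: str = CATALYTIC_PATTERN,
) -> pd.DataFrame:
    """Threshold sweep of trimmed lid length and hydrophobicity per node.

    One row per (node, threshold), sorted by node then threshold, plus a
    per-node check that both conserved motif classes are present in the
    full MAP sequence. ``hydrophobic_percent`` is NaN for empty lids.
    """
    if node_ids is None:
        node_ids = sorted(reconstructions)
    rows = []
    for node_id in node_ids:
        rec = reconstructions[node_id]
        hits = find_motifs(rec.map_sequence, oxyanion_pattern, catalytic_pattern)
        lid = ancestral_lid(rec, columns)
        for theta in thresholds:
            trimmed = trim_by_posterior(lid, theta)
            if len(trimmed):
                count, percent = hydrophobic_fraction(
                    trimmed.residues, hydrophobic_set
                )
            else:
                count, percent = 0, float("nan")
            rows.append(
                {
                    "node_id": node_id,
                    "threshold": theta,
                    "lid_length": len(trimmed),
                    "hydrophobic_count": count,
                    "hydrophobic_percent": percent,
                    "has_oxyanion_motif": bool(hits.oxyanion),
                    "has_catalytic_motif": bool(hits.catalytic),
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["node_id", "threshold"], ignore_index=True
    )
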