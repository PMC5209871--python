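"""Candidate screening for versatile-lipase-like sequences.

Four criteria, applied in a fixed order purely so that failure reasons
are reported stably (all criteria are always evaluated):

1. global pairwise identity to the reference lipase >= 30%,
2. a predicted N-terminal signal peptide,
3. both conserved motif classes present — the oxyanion-hole pattern
   ``GGG[FL]`` and the catalytic-serine pattern ``G[EQ]SAG`` (a
   GxSxG-type serine-hydrolase signature),
4. a lid region of >= 20 residues, located by aligning the candidate to
   a reference with known lid coordinates.

The signal-peptide call is a transparent hydropathy heuristic standing
in for an external predictor: the sequence must start with Met and some
8-residue window within the first 35 residues must reach mean
Kyte-Doolittle hydropathy >= 1.6 (a hydrophobic h-region). Externally
computed signal-peptide flags can be injected per record instead.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import pandas as pd

from .align import AlignParams, PairwiseAlignment, global_align, percent_identity
from .io_core import GAP, ProteinRecord

#: Default motif patterns (regular expressions, ungapped sequence).
OXYANION_PATTERN = "GGG[FL]"
CATALYTIC_PATTERN = "G[EQ]SAG"

#: Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

SIGNAL_WINDOW = 8
SIGNAL_SEARCH_END = 35        # h-region window must start within 1..35
SIGNAL_MIN_HYDROPATHY = 1.6
SIGNAL_MAX_CLEAVAGE = 40
MIN_SIGNAL_LENGTH = 25


@dataclass
class MotifHits:
    """Non-overlapping motif matches, left to right (0-based positions)."""

    oxyanion: list[tuple[int, str]]
    catalytic: list[tuple[int, str]]


def find_motifs(
    record: ProteinRecord | str,
    oxyanion_pattern: str = OXYANION_PATTERN,
    catalytic_pattern: str = CATALYTIC_PATTERN,
) -> MotifHits:
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if GAP in seq:
        raise ValueError("find_motifs expects an ungapped sequence")
    return MotifHits(
        oxyanion=[(m.start(), m.group()) for m in re.finditer(oxyanion_pattern, seq)],
        catalytic=[(m.start(), m.group()) for m in re.finditer(catalytic_pattern, seq)],
    )


@dataclass
class SignalPeptideCall:
    present: bool
    h_region_score: float
    cleavage_guess: int | None  # 0-based position; None when absent
    reason: str | None = None


def predict_signal_peptide(record: ProteinRecord | str) -> SignalPeptideCall:
    """Hydropathy-window heuristic for an N-terminal signal peptide."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    seq = seq.replace(GAP, "")
    if len(seq) < MIN_SIGNAL_LENGTH:
        return SignalPeptideCall(False, 0.0, None, reason="too_short")
    best_score = float("-inf")
    best_end = None
    limit = min(SIGNAL_SEARCH_END, len(seq))
    for start in range(0, limit - SIGNAL_WINDOW + 1):
        window = seq[start : start + SIGNAL_WINDOW]
        score = sum(KYTE_DOOLITTLE[c] for c in window) / SIGNAL_WINDOW
        if score > best_score:
            best_score = score
            best_end = start + SIGNAL_WINDOW
    present = seq.startswith("M") and best_score >= SIGNAL_MIN_HYDROPATHY
    cleavage = None
    if present:
        cleavage = min(best_end + 5, SIGNAL_MAX_CLEAVAGE)
    return SignalPeptideCall(present, float(best_score), cleavage)


@dataclass
class LidExtract:
    """Candidate residues falling in the reference's lid columns."""

    residues: str
    interval: tuple[int, int] | None  # 0-based half-open on the candidate
    length: int


def extract_lid(
    candidate: ProteinRecord,
    reference: ProteinRecord,
    params: AlignParams | None = None,
) -> LidExtract:
    """Map the reference's annotated lid onto a candidate by alignment."""
    if "lid" not in reference.features:
        raise ValueError("reference record carries no 'lid' feature")
    lid_start, lid_end = reference.features["lid"]
    pw = global_align(candidate, reference, params)
    residues = []
    first = last = None
    ci = ri = 0
    for x, y in zip(pw.gapped_a, pw.gapped_b):
        in_lid = y != GAP and lid_start <= ri < lid_end
        if in_lid and x != GAP:
            residues.append(x)
            if first is None:
                first = ci
            last = ci
        if x != GAP:
            ci += 1
        if y != GAP:
            ri += 1
    interval = (first, last + 1) if residues else None
    return LidExtract("".join(residues), interval, len(residues))


@dataclass
class CandidateResult:
    id: str
    identity_to_reference: float
    signal: SignalPeptideCall
    motifs: MotifHits
    lid_length: int
    decision: str
    reasons: list[str]


@dataclass
class ScreenConfig:
    min_identity: float = 0.30
    min_lid: int = 20
    min_length: int | None = None   # the length criterion has no fixed bound
    max_length: int | None = None
    params: AlignParams | None = None
    #: optional externally computed signal-peptide flags, id -> bool
    signal_flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class ScreeningReport:
    rows: list[CandidateResult]
    summary: dict[str, int]

    @property
    def accepted_ids(self) -> list[str]:
        return [r.id for r in self.rows if r.decision == "accepted"]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.rows],
                "identity_pct": [
                    round(100 * r.identity_to_reference, 1) for r in self.rows
                ],
                "signal_peptide": [r.signal.present for r in self.rows],
                "n_oxyanion": [len(r.motifs.oxyanion) for r in self.rows],
                "n_catalytic": [len(r.motifs.catalytic) for r in self.rows],
                "lid_length": [r.lid_length for r in self.rows],
                "decision": [r.decision for r in self.rows],
                "reasons": [";".join(r.reasons) for r in self.rows],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def summary_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)


def screen_candidates(
    records: list[ProteinRecord],
    reference: ProteinRecord,
    config: ScreenConfig | None = None,
) -> ScreeningReport:
    """Apply the four selection criteria; every failure is recorded."""
    if not records:
        raise ValueError("no candidate records to screen")
    config = config or ScreenConfig()
    params = config.params or AlignParams()
    rows: list[CandidateResult] = []
    for rec in records:
        reasons: list[str] = []
        ident = percent_identity(global_align(rec, reference, params))
        if ident < config.min_identity:
            reasons.append("low_identity")
        if rec.id in config.signal_flags:
            sig = SignalPeptideCall(
                bool(config.signal_flags[rec.id]), float("nan"), None,
                reason="external_flag",
            )
        else:
            sig = predict_signal_peptide(rec)
        if not sig.present:
            reasons.append("no_signal_peptide")
        hits = find_motifs(rec)
        if not (hits.oxyanion and hits.catalytic):
            reasons.append("missing_motifs")
        lid = extract_lid(rec, reference, params)
        if lid.length < config.min_lid:
            reasons.append("lid_too_short")
        n = len(rec.sequence)
        if (config.min_length is not None and n < config.min_length) or (
            config.max_length is not None and n > config.max_length
        ):
            reasons.append("bad_length")
        rows.append(
            CandidateResult(
                id=rec.id,
                identity_to_reference=ident,
                signal=sig,
                motifs=hits,
                lid_length=lid.length,
                decision="accepted" if not reasons else "rejected",
                reasons=reasons,
            )
        )
    summary: dict[str, int] = {
        "n_candidates": len(rows),
        "n_accepted": sum(r.decision == "accepted" for r in rows),
        "n_rejected": sum(r.decision == "rejected" for r in rows),
    }
    for row in rows:
        for reason in row.reasons:
            summary[reason] = summary.get(reason, 0) + 1
    return ScreeningReport(rows, summary)
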