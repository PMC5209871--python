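"""Pairwise global alignment, percent identity and a progressive MSA.

The pairwise aligner is an affine-gap Needleman-Wunsch-Gotoh with a
documented deterministic tie-break (match/mismatch preferred over a gap
in the first sequence, preferred over a gap in the second). A gap run of
length ``k`` costs ``gap_open + gap_extend * (k - 1)``.

The progressive multiple aligner is an explicit convenience substitute
for an external MSA tool: a UPGMA guide tree over pairwise identity
distances, then profile-profile Needleman-Wunsch with mean-of-pairs
column scoring. The rest of the pipeline accepts a precomputed aligned
FASTA, so tool-based workflows can bypass it entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_core import GAP, MultipleAlignment, ProteinRecord

logger = logging.getLogger(__name__)

_NEG = float("-inf")


def load_scoring_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """Named substitution matrix as a symmetric char-pair dict."""
    mat = substitution_matrices.load(name)
    scores: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            scores[(a, b)] = float(mat[a, b])
    return scores


@dataclass
class AlignParams:
    """Scoring parameters: substitution matrix plus affine gap penalties."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    scores: dict[tuple[str, str], float] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.scores is None:
            self.scores = load_scoring_matrix(self.matrix_name)

    def score(self, a: str, b: str) -> float:
        return self.scores[(a, b)]


@dataclass
class PairwiseAlignment:
    """Global alignment of two sequences."""

    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped sequences must have equal length")
        if any(
            x == GAP and y == GAP
            for x, y in zip(self.gapped_a, self.gapped_b)
        ):
            raise ValueError("gap-gap column in pairwise alignment")

    @property
    def identity(self) -> float:
        return percent_identity(self)


def global_align(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    params: AlignParams | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment under affine-gap Gotoh scoring.

    Tie-breaking is deterministic: at equal score the traceback prefers
    a match/mismatch column, then a gap in ``a``, then a gap in ``b``.
    """
    params = params or AlignParams()
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    if GAP in sa or GAP in sb:
        raise ValueError("inputs to global_align must be ungapped")

    n, m = len(sa), len(sb)
    open_, ext = params.gap_open, params.gap_extend
    # state matrices: M match/mismatch, GA gap in a (consumes b), GB gap in b
    M = np.full((n + 1, m + 1), _NEG)
    GA = np.full((n + 1, m + 1), _NEG)
    GB = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        GA[0, j] = -(open_ + ext * (j - 1))
    for i in range(1, n + 1):
        GB[i, 0] = -(open_ + ext * (i - 1))

    for i in range(1, n + 1):
        row_s = [params.score(sa[i - 1], y) for y in sb]
        Mi, Mi1 = M[i], M[i - 1]
        GAi, GAi1 = GA[i], GA[i - 1]
        GBi, GBi1 = GB[i], GB[i - 1]
        for j in range(1, m + 1):
            Mi[j] = row_s[j - 1] + max(Mi1[j - 1], GAi1[j - 1], GBi1[j - 1])
            GAi[j] = max(Mi[j - 1] - open_, GAi[j - 1] - ext,
                         GBi[j - 1] - open_)
            GBi[j] = max(Mi1[j] - open_, GBi1[j] - ext, GAi1[j] - open_)

    # traceback with the documented state priority M > GA > GB
    i, j = n, m
    state = max(("M", "GA", "GB"),
                key=lambda s: ({"M": M, "GA": GA, "GB": GB}[s][i, j],
                               {"M": 2, "GA": 1, "GB": 0}[s]))
    score = {"M": M, "GA": GA, "GB": GB}[state][n, m]
    out_a: list[str] = []
    out_b: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            target = M[i, j] - params.score(sa[i - 1], sb[j - 1])
            i, j = i - 1, j - 1
            if abs(M[i, j] - target) <= eps:
                state = "M"
            elif abs(GA[i, j] - target) <= eps:
                state = "GA"
            else:
                state = "GB"
        elif state == "GA":
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            val = GA[i, j]
            j -= 1
            if abs(M[i, j] - open_ - val) <= eps:
                state = "M"
            elif abs(GA[i, j] - ext - val) <= eps:
                state = "GA"
            else:
                state = "GB"
        else:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            val = GB[i, j]
            i -= 1
            if abs(M[i, j] - open_ - val) <= eps:
                state = "M"
            elif abs(GB[i, j] - ext - val) <= eps:
                state = "GB"
            else:
                state = "GA"
        if i == 0 and j > 0:
            state = "GA"
        elif j == 0 and i > 0:
            state = "GB"
    return PairwiseAlignment("".join(reversed(out_a)),
                             "".join(reversed(out_b)), float(score))


def percent_identity(alignment: PairwiseAlignment) -> float:
    """Identical-residue columns over aligned columns holding >= 1 residue.

    The denominator convention is stated rather than inherited from any
    particular alignment program; gap-gap columns cannot occur.
    """
    same = 0
    total = 0
    for x, y in zip(alignment.gapped_a, alignment.gapped_b):
        total += 1
        if x == y and x != GAP:
            same += 1
    return same / total if total else 0.0


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def _profile_columns(rows: list[str]) -> list[dict[str, float]]:
    ncol = len(rows[0])
    cols = []
    for j in range(ncol):
        freq: dict[str, float] = {}
        for row in rows:
            ch = row[j]
            freq[ch] = freq.get(ch, 0.0) + 1.0
        k = len(rows)
        cols.append({ch: c / k for ch, c in freq.items()})
    return cols


def _align_profiles(
    rows_a: list[str], rows_b: list[str], params: AlignParams
) -> tuple[list[str], list[str]]:
    """Linear-gap profile-profile NW with mean-of-pairs column scores."""
    cols_a = _profile_columns(rows_a)
    cols_b = _profile_columns(rows_b)
    gap_cost = params.gap_open / 2.0

    def col_score(fa: dict[str, float], fb: dict[str, float]) -> float:
        s = 0.0
        for x, wx in fa.items():
            for y, wy in fb.items():
                if x == GAP or y == GAP:
                    continue
                s += wx * wy * params.score(x, y)
        return s

    n, m = len(cols_a), len(cols_b)
    D = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        D[i, 0] = -gap_cost * i
    for j in range(1, m + 1):
        D[0, j] = -gap_cost * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = max(
                D[i - 1, j - 1] + col_score(cols_a[i - 1], cols_b[j - 1]),
                D[i, j - 1] - gap_cost,
                D[i - 1, j] - gap_cost,
            )
    # traceback, diagonal preferred, then gap in profile a
    i, j = n, m
    path: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(
            D[i, j] - (D[i - 1, j - 1] + col_score(cols_a[i - 1], cols_b[j - 1]))
        ) <= eps:
            path.append("D"); i -= 1; j -= 1
        elif j > 0 and abs(D[i, j] - (D[i, j - 1] - gap_cost)) <= eps:
            path.append("A"); j -= 1
        else:
            path.append("B"); i -= 1
    path.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for step in path:
        if step == "D":
            for k, row in enumerate(rows_a):
                out_a[k] += row[i]
            for k, row in enumerate(rows_b):
                out_b[k] += row[j]
            i += 1; j += 1
        elif step == "A":
            for k in range(len(rows_a)):
                out_a[k] += GAP
            for k, row in enumerate(rows_b):
                out_b[k] += row[j]
            j += 1
        else:
            for k, row in enumerate(rows_a):
                out_a[k] += row[i]
            for k in range(len(rows_b)):
                out_b[k] += GAP
            i += 1
    return out_a, out_b


def _strip_all_gap_columns(rows: list[str]) -> list[str]:
    keep = [j for j in range(len(rows[0]))
            if any(row[j] != GAP for row in rows)]
    return ["".join(row[j] for j in keep) for row in rows]


def progressive_msa(
    records: list[ProteinRecord], params: AlignParams | None = None
) -> MultipleAlignment:
    """Progressive multiple alignment (UPGMA guide tree, profile merges).

    Deterministic given input order. A single record is returned as a
    trivial alignment with a warning.
    """
    params = params or AlignParams()
    if len(records) == 1:
        logger.warning("progressive_msa called with a single record")
        return MultipleAlignment([records[0]])
    if len(records) == 2:
        pw = global_align(records[0], records[1], params)
        return MultipleAlignment([
            ProteinRecord(records[0].id, pw.gapped_a),
            ProteinRecord(records[1].id, pw.gapped_b),
        ])

    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pw = global_align(records[i], records[j], params)
            dist[i, j] = dist[j, i] = 1.0 - percent_identity(pw)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")

    # cluster id -> (ordered member indices, gapped rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].sequence]) for i in range(n)
    }
    for step, (ia, ib, _, _) in enumerate(Z):
        mem_a, rows_a = clusters.pop(int(ia))
        mem_b, rows_b = clusters.pop(int(ib))
        out_a, out_b = _align_profiles(rows_a, rows_b, params)
        clusters[n + step] = (mem_a + mem_b, out_a + out_b)

    members, rows = clusters.popitem()[1]
    rows = _strip_all_gap_columns(rows)
    order = np.argsort(members)
    recs = [ProteinRecord(records[members[k]].id, rows[k]) for k in order]
    return MultipleAlignment(recs)
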