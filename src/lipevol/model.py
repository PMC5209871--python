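"""WAG(+F) amino-acid substitution model and transition probabilities.

The model is a general time-reversible continuous-time Markov chain on
the 20 amino acids, ``Q_ij = S_ij * pi_j`` for ``i != j``, where ``S`` is
the symmetric WAG exchangeability matrix and ``pi`` the equilibrium
frequencies — either the WAG defaults or, under "+F", frequencies
counted from the analyzed alignment. ``Q`` is scaled so the expected
substitution rate at equilibrium, ``-sum_i pi_i Q_ii``, equals 1, i.e.
branch lengths are expected substitutions per site.

Transition probabilities ``P(t) = expm(Q t)`` are computed through the
symmetric eigendecomposition of ``Pi^(1/2) Q Pi^(-1/2)``, which is exact
and numerically stable for reversible models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .io_core import AA_INDEX, ALPHABET, MISSING, MultipleAlignment

N_STATES = 20
#: Floor applied to "+F" frequencies so zero-count residues keep the
#: chain irreducible and the model invertible.
FREQ_FLOOR = 1e-4


@dataclass
class SubstitutionModel:
    """Reversible amino-acid substitution model.

    Attributes
    ----------
    S:
        Symmetric 20x20 exchangeability matrix, zero diagonal.
    pi:
        Equilibrium frequencies, strictly positive, summing to 1.
    Q:
        Rate matrix, rows sum to 0, unit expected rate.
    """

    S: np.ndarray
    pi: np.ndarray
    Q: np.ndarray = field(init=False)
    # eigendecomposition of the symmetrized rate matrix, cached for P(t)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if S.shape != (N_STATES, N_STATES) or pi.shape != (N_STATES,):
            raise ValueError("S must be 20x20 and pi length 20")
        if np.any(pi <= 0):
            raise ValueError("equilibrium frequencies must be positive")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalize to one expected substitution per unit branch length
        rate = -np.dot(pi, np.diag(Q))
        Q /= rate
        self.S, self.pi, self.Q = S, pi, Q

        sqrt_pi = np.sqrt(pi)
        B = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]  # Pi^(1/2) Q Pi^(-1/2)
        eigvals, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = eigvals
        self._right = U / sqrt_pi[:, None]      # Pi^(-1/2) U
        self._left = (U * sqrt_pi[:, None]).T   # U^T Pi^(1/2)

    def transition_matrix(self, t: float) -> np.ndarray:
        """``P(t)``: rows sum to 1, entries clipped into [0, 1]."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        P = (self._right * np.exp(self._eigvals * t)) @ self._left
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def _load_wag_table() -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("lipevol.data").joinpath("wag.dat").read_text()
    rows = [
        line.split()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    S = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(rows[:19], start=1):
        for j, val in enumerate(row):
            S[i, j] = S[j, i] = float(val)
    pi = np.array([float(x) for x in rows[19]])
    return S, pi


def wag_exchangeabilities() -> np.ndarray:
    """The WAG symmetric exchangeability matrix (embedded table)."""
    return _load_wag_table()[0]


def wag_frequencies() -> np.ndarray:
    """The WAG default equilibrium frequencies (embedded table)."""
    return _load_wag_table()[1]


def empirical_frequencies(alignment: MultipleAlignment) -> np.ndarray:
    """Observed residue frequencies over all non-gap, non-``X`` characters.

    Frequencies are floored at ``1e-4`` and renormalized so every state
    stays reachable (zero-count residues would otherwise break
    reversibility and matrix inversion).
    """
    counts = np.zeros(N_STATES)
    for rec in alignment.records:
        for ch in rec.sequence:
            if ch not in MISSING:
                counts[AA_INDEX[ch]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no non-gap characters")
    freqs = np.maximum(counts / total, FREQ_FLOOR)
    return freqs / freqs.sum()


def build_wag_model(
    frequency_mode: str = "wag_default",
    alignment: MultipleAlignment | None = None,
) -> SubstitutionModel:
    """Construct WAG or WAG+F.

    ``frequency_mode`` is ``"wag_default"`` (frequencies from the WAG
    publication) or ``"empirical_plus_F"`` (frequencies counted from
    ``alignment``).
    """
    S, pi_default = _load_wag_table()
    if frequency_mode == "wag_default":
        pi = pi_default
    elif frequency_mode == "empirical_plus_F":
        if alignment is None:
            raise ValueError("empirical_plus_F requires an alignment")
        pi = empirical_frequencies(alignment)
    else:
        raise ValueError(f"unknown frequency mode {frequency_mode!r}")
    return SubstitutionModel(S=S, pi=pi)


def equal_rates_model() -> SubstitutionModel:
    """Uniform-frequency, equal-exchangeability 20-state test model.

    Under unit-rate normalization this chain has the closed form
    ``P_ii(t) = 1/20 + (19/20) exp(-(20/19) t)``, which makes it a handy
    analytic check on the eigendecomposition machinery.
    """
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    pi = np.full(N_STATES, 1.0 / N_STATES)
    return SubstitutionModel(S=S, pi=pi)


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """Functional alias for :meth:`SubstitutionModel.transition_matrix`."""
    return model.transition_matrix(t)
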