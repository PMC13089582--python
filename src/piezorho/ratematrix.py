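"""Property-partitioned codon rate matrix and its transition probabilities.

The instantaneous rate from sense codon i to j is zero when i and j differ at
more than one nucleotide position; otherwise it is pi_j times kappa for a
transition, further scaled by omega for a conservative nonsynonymous change or
by gamma for a radical one (synonymous changes carry no omega/gamma factor).
Setting gamma = omega collapses the model to the standard Goldman–Yang codon
model. Q is rescaled so the expected substitution rate at stationarity is one,
making branch lengths expected substitutions per codon and comparable across
partitions.

Because the chain is time-reversible (pi_i q_ij = pi_j q_ji by construction),
exp(Qt) is computed through the symmetric similarity transform
diag(sqrt(pi)) Q diag(1/sqrt(pi)), eigendecomposed once per parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetics import STANDARD_CODE, GeneticCode
from .property_partition import RadicalPartition


@dataclass(frozen=True)
class WSNParameters:
    """kappa: transition/transversion ratio; omega: conservative-nonsynonymous
    rate scaler; gamma: radical-nonsynonymous rate scaler."""

    kappa: float
    omega: float
    gamma: float

    def __post_init__(self):
        for name in ("kappa", "omega", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def validate_frequencies(pi: np.ndarray, n: int = 61) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (n,):
        raise ValueError(f"frequency vector must have length {n}")
    if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("codon frequencies must be nonnegative and sum to 1")
    return pi / pi.sum()


def empirical_codon_frequencies(matrix: np.ndarray, code: GeneticCode = STANDARD_CODE,
                                method: str = "F3X4") -> np.ndarray:
    """Codon equilibrium frequencies estimated from observed codon counts.

    F3X4: product of position-specific nucleotide frequencies, renormalized
    over sense codons (the default; not counted as free parameters).
    F61: empirical codon proportions with a small pseudocount.
    """
    observed = matrix[matrix >= 0]
    if method == "F61":
        counts = np.bincount(observed, minlength=code.n_codons).astype(float) + 0.5
        return counts / counts.sum()
    if method != "F3X4":
        raise ValueError(f"unknown frequency method {method!r}")
    pos_freq = np.zeros((3, 4))
    nuc_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for idx in observed:
        for p, nt in enumerate(code.codons[idx]):
            pos_freq[p, nuc_index[nt]] += 1
    pos_freq += 0.5
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, nuc_index[c[0]]]
            * pos_freq[1, nuc_index[c[1]]]
            * pos_freq[2, nuc_index[c[2]]]
            for c in code.codons
        ]
    )
    return pi / pi.sum()


def build_rate_matrix(params: WSNParameters, partition: RadicalPartition,
                      freqs: np.ndarray, code: GeneticCode = STANDARD_CODE,
                      normalize: bool = True) -> np.ndarray:
    """The n x n (61 x 61 standard-code) instantaneous rate matrix Q."""
    pi = validate_frequencies(freqs, code.n_codons)
    n = code.n_codons
    Q = np.zeros((n, n))
    for i, j, _pos, transition in code.single_step_neighbours():
        ci, cj = code.codons[i], code.codons[j]
        rate = pi[j] * (params.kappa if transition else 1.0)
        if code.aa(ci) != code.aa(cj):
            if partition.is_radical(ci, cj):
                rate *= params.gamma
            else:
                rate *= params.omega
        Q[i, j] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mean_rate = -float(pi @ np.diag(Q))
        if mean_rate <= 0:
            raise ValueError("degenerate rate matrix (zero expected rate)")
        Q /= mean_rate
    return Q


class ReversibleRateMatrix:
    """Eigendecomposed reversible Q for cheap repeated matrix exponentials."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        self.pi = validate_frequencies(pi, Q.shape[0])
        sqrt_pi = np.sqrt(self.pi)
        sym = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        sym = 0.5 * (sym + sym.T)  # symmetrize away roundoff
        eigval, eigvec = np.linalg.eigh(sym)
        self._eigval = eigval
        self._left = eigvec / sqrt_pi[:, None]   # D^{-1/2} U
        self._right = (eigvec * sqrt_pi[:, None]).T  # U^T D^{1/2}

    def expm(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one, entries clipped at zero."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_probabilities(Q: np.ndarray, t: float,
                             pi: np.ndarray | None = None) -> np.ndarray:
    """exp(Qt) as a stochastic matrix (spec op)."""
    if pi is None:
        from scipy.linalg import expm

        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = expm(Q * t)
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)
    return ReversibleRateMatrix(Q, pi).expm(t)
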