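"""HKY85 nucleotide substitution model.

The rate matrix distinguishes transitions (A<->G, C<->T; rate kappa*pi_j)
from transversions (rate pi_j) and is normalised so that branch lengths are
measured in expected substitutions per site. Transition probabilities P(t)
are obtained from the spectral decomposition of the reversible rate matrix
(symmetrised with the pi^{1/2} similarity transform), which is exact and
cheap to re-evaluate for the many branch distances an MCMC visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# transition partners (purine<->purine, pyrimidine<->pyrimidine)
_TRANSITION = np.zeros((4, 4), dtype=bool)
for _a, _b in (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")):
    _TRANSITION[BASE_INDEX[_a], BASE_INDEX[_b]] = True


@dataclass
class HkyModel:
    """HKY85 model with transition/transversion parameter kappa and
    stationary frequencies pi (order A, C, G, T)."""

    kappa: float = 2.0
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (4,):
            raise ValueError("pi must be a 4-vector")
        if not np.all(self.pi > 0):
            raise ValueError("pi must be strictly positive")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must sum to 1")
        self.pi = self.pi / self.pi.sum()
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise ValueError("kappa must be positive and finite")
        self._decompose()

    def rate_matrix(self) -> np.ndarray:
        """Normalised HKY rate matrix Q (rows sum to 0, -sum_i pi_i Q_ii = 1)."""
        Q = np.where(_TRANSITION, self.kappa, 1.0) * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(self.pi, np.diag(Q))
        return Q / scale

    def _decompose(self):
        Q = self.rate_matrix()
        d = np.sqrt(self.pi)
        S = (Q * d[:, None]) / d[None, :]  # symmetric similarity transform
        S = 0.5 * (S + S.T)
        evals, U = np.linalg.eigh(S)
        self._evals = evals
        self._left = U / d[:, None]   # rows scaled: D^{-1/2} U
        self._right = (U * d[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t): 4x4 matrix of P(observed base j | starting base i, distance t)."""
        if t < 0:
            raise ValueError(f"negative branch distance t={t}")
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrix_raw(self, t: float) -> np.ndarray:
        """As `transition_matrix` but without the clip/renormalise polish;
        entries may deviate from [0,1] by rounding error only. Used in the
        likelihood hot path, where probabilities are floored anyway."""
        return (self._left * np.exp(self._evals * t)) @ self._right


def hky_transition_matrix(model: HkyModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


def estimate_pi(seqs, pseudocount: float = 1.0) -> np.ndarray:
    """Stationary frequencies from base counts over sequences (gaps/N ignored)."""
    counts = np.full(4, float(pseudocount))
    for s in seqs:
        for b, i in BASE_INDEX.items():
            counts[i] += s.count(b)
    return counts / counts.sum()


def model_from_msa(msa, kappa: float = 2.0) -> HkyModel:
    return HkyModel(kappa=kappa, pi=estimate_pi(msa.seqs))
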