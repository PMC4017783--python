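"""Dirichlet prior/posterior over population haplotype frequencies.

The population haplotype frequency vector theta gets a symmetric Dirichlet
prior.  Because haplotype draws are multinomial, the posterior after
observing assignment counts is again Dirichlet, and the marginal predictive
probability of a new individual's haplotype draws is a ratio of
multivariate beta functions, computed here in log space throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln


@dataclass(frozen=True)
class SufficientStats:
    """Dirichlet parameters aligned to a haplotype universe.

    ``rho = prior_pseudocount + accumulated haplotype counts``.
    """

    rho: np.ndarray
    prior_pseudocount: float

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "rho", rho)
        if rho.ndim != 1 or rho.size == 0:
            raise ValueError("rho must be a non-empty vector")
        if not np.all(rho > 0):
            raise ValueError("Dirichlet parameters must be positive")

    @property
    def size(self) -> int:
        return int(self.rho.size)


def init_prior(M: int, epsilon: float = 1.0) -> SufficientStats:
    """Symmetric Dirichlet prior with all parameters equal to ``epsilon``."""
    if M < 1:
        raise ValueError("empty haplotype universe")
    if epsilon <= 0:
        raise ValueError("prior pseudocount must be positive")
    return SufficientStats(np.full(M, float(epsilon)), float(epsilon))


def count_vector(assignment, universe) -> np.ndarray:
    """Occurrence counts of each universe haplotype in ``assignment``."""
    r = np.zeros(len(universe), dtype=np.int64)
    for h in assignment.haplotypes:
        idx = universe.index.get(h)
        if idx is None:
            raise KeyError(
                f"haplotype {h} not in universe; build the universe from all "
                "assignment lists first"
            )
        r[idx] += 1
    return r


def _check_aligned(s: SufficientStats, r: np.ndarray) -> np.ndarray:
    r = np.asarray(r)
    if r.shape != s.rho.shape:
        raise ValueError(f"count vector length {r.size} != stats length {s.size}")
    return r


def posterior_update(s: SufficientStats, r: np.ndarray) -> SufficientStats:
    """Conjugate update: element-wise ``rho + r`` (input left unchanged)."""
    r = _check_aligned(s, r)
    return SufficientStats(s.rho + r, s.prior_pseudocount)


def log_predictive_weight(s: SufficientStats, r: np.ndarray) -> float:
    """``ln B(rho + r) - ln B(rho)``: the log Dirichlet-multinomial
    predictive probability of the ordered draw sequence with counts ``r``."""
    r = _check_aligned(s, r)
    num = float(np.sum(gammaln(s.rho + r) - gammaln(s.rho)))
    den = float(gammaln(s.rho.sum() + r.sum()) - gammaln(s.rho.sum()))
    return num - den


def posterior_mean(s: SufficientStats) -> np.ndarray:
    """Posterior mean frequencies ``rho_k / sum(rho)``; sums to 1."""
    return s.rho / s.rho.sum()
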